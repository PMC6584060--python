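"""Synthetic beta-value matrices with planted group-differential CpGs.

The generator emulates the statistical structure the downstream analysis
assumes: bounded beta values, two balanced classes, and a small number of
discriminating CpGs hidden among a large null background. Values are drawn as
the inverse logit of a Gaussian (logit-normal), which keeps a linear effect on
the transformed (M-value) scale while guaranteeing the (0, 1) bound. Each
feature gets its own baseline logit mean so features span low, intermediate and
high methylation, reproducing the U-shaped marginal typical of array data.
Planted features receive a logit-scale mean shift in the allergic class whose
sign alternates across features, so both hyper- and hypo-methylated markers
occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._seeds import child_seed
from .io import ALLERGIC, SENSITIZED, BetaMatrix, LabeledCohort

import pandas as pd


class SyntheticSpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the logit-normal generator.

    n_per_class: samples per class (29 each mirrors the study cohort size).
    n_features: total CpGs; default 5,000 keeps desk-scale runs fast but the
        generator scales to full-array sizes (~4e5).
    n_informative: number of planted group-differential CpGs.
    effect_delta: class mean shift on the logit scale for planted CpGs.
    noise_sd: logit-scale within-class standard deviation.
    baseline_sd: spread of per-feature baseline logit means.
    """

    n_per_class: int = 29
    n_features: int = 5000
    n_informative: int = 20
    effect_delta: float = 1.0
    noise_sd: float = 0.5
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise SyntheticSpecError("n_per_class must be >= 1")
        if self.n_features < 1:
            raise SyntheticSpecError("n_features must be >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise SyntheticSpecError("need 0 <= n_informative <= n_features")
        if self.effect_delta < 0:
            raise SyntheticSpecError("effect_delta must be >= 0")
        if self.noise_sd <= 0:
            raise SyntheticSpecError("noise_sd must be > 0")


def generate(spec: SyntheticSpec):
    """Generate (BetaMatrix, LabeledCohort, planted feature IDs) from a spec.

    Deterministic given ``spec.seed``. The planted-feature indices are drawn
    from a child RNG stream separate from the value stream, so the generated
    values do not depend on ``n_informative``: planting with ``effect_delta=0``
    is bit-identical to all-null generation under the same seed.
    """
    spec.validate()
    n = 2 * spec.n_per_class
    feature_ids = [f"cg{i:08d}" for i in range(spec.n_features)]
    sample_ids = [f"A{i + 1:03d}" for i in range(spec.n_per_class)] + [
        f"S{i + 1:03d}" for i in range(spec.n_per_class)
    ]
    labels = (ALLERGIC,) * spec.n_per_class + (SENSITIZED,) * spec.n_per_class

    rng = np.random.default_rng(spec.seed)
    plant_rng = np.random.default_rng(child_seed(spec.seed, "plant"))
    planted_idx = np.sort(
        plant_rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    )

    mu = rng.normal(0.0, spec.baseline_sd, size=spec.n_features)
    logits = mu[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_features, n))
    # shift planted CpGs in the allergic block, alternating direction
    for j, idx in enumerate(planted_idx):
        sign = 1.0 if j % 2 == 0 else -1.0
        logits[idx, : spec.n_per_class] += sign * spec.effect_delta

    values = expit(logits)
    matrix = BetaMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids))
    cohort = LabeledCohort(tuple(sample_ids), labels)
    planted_ids = {feature_ids[i] for i in planted_idx}
    return matrix, cohort, planted_ids


def expected_beta_shift(mu: float, delta: float, sd: float, n_quad: int = 201) -> float:
    """Expected between-class beta-scale mean difference for a planted feature.

    Computes E[expit(mu + delta + sd Z)] - E[expit(mu + sd Z)] by Gauss-Hermite
    quadrature; used to check generator calibration.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    w = weights / weights.sum()
    shifted = float(np.sum(w * expit(mu + delta + sd * nodes)))
    base = float(np.sum(w * expit(mu + sd * nodes)))
    return shifted - base
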