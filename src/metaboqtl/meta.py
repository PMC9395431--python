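"""Inverse-variance-weighted meta-analysis and the validation rule.

Discovery hits are validated in external cohorts by fixed-effect IVW
combination of the per-cohort effect estimates; a hit validates nominally
at meta p < 0.05 with a direction of effect consistent with discovery, and
at the Bonferroni level when p additionally clears 0.05 divided by the
number of associations tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "ivw_meta", "validate"]


@dataclass
class MetaResult:
    """Fixed-effect IVW combination of per-cohort (beta, SE) estimates."""

    beta: float
    se: float
    z: float
    p: float
    cohort_betas: list[float] = field(default_factory=list)
    cohort_ses: list[float] = field(default_factory=list)
    q: float = 0.0
    i2: float = 0.0


def ivw_meta(estimates: list[tuple[float, float]]) -> MetaResult:
    """Combine estimates with weights 1/SE^2.

    beta = sum(w_i b_i) / sum(w_i), SE = 1/sqrt(sum(w_i)); two-sided normal
    p. Cochran's Q and I^2 are reported for information only and play no
    role in the validation decision.
    """
    if not estimates:
        raise ValueError("meta-analysis requires at least one estimate")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (betas - beta) ** 2))
    dfq = len(estimates) - 1
    i2 = float(max(0.0, (q - dfq) / q)) if q > 0 and dfq > 0 else 0.0
    return MetaResult(
        beta=beta, se=se, z=float(z), p=p,
        cohort_betas=betas.tolist(), cohort_ses=ses.tolist(), q=q, i2=i2,
    )


def validate(
    discovery_beta: float,
    meta: MetaResult | None,
    p_cut: float = 0.05,
    n_tested: int | None = None,
    all_cohorts_consistent: bool = True,
) -> str:
    """Validation status of a discovery hit in external cohorts.

    Returns ``validated_bonferroni`` when the meta p clears 0.05/n_tested
    with a consistent direction, ``validated_nominal`` at meta p < 0.05
    with a consistent direction, ``not_validated`` otherwise, and
    ``unavailable`` when no meta result exists. By default direction
    consistency requires every available cohort beta to share the
    discovery sign; ``all_cohorts_consistent=False`` relaxes this to the
    combined estimate's sign only.
    """
    if meta is None:
        return "unavailable"
    if all_cohorts_consistent:
        consistent = all(np.sign(b) == np.sign(discovery_beta) for b in meta.cohort_betas)
    else:
        consistent = np.sign(meta.beta) == np.sign(discovery_beta)
    if not consistent or meta.p >= p_cut:
        return "not_validated"
    if n_tested and meta.p < p_cut / n_tested:
        return "validated_bonferroni"
    return "validated_nominal"
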