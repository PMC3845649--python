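"""Relative qPCR amplification for copy-number verification.

The contracted quantity is relative amplification E^(Cp_ref) / E^(Cp_test),
where E is the per-cycle amplification efficiency (dimensionless, in
(1, 2]) and Cp the crossing point of the reference and test genes; a
template present at c copies crosses log_E(c) cycles earlier than a
single-copy template, so the across-strain fold change of this ratio for
one gene recovers the copy ratio.  Ratios are never compared across genes
— they depend on primer efficiencies, so only within-gene, across-strain
folds carry meaning.

Replicates are aggregated by arithmetic mean on the Cp scale (the
near-Gaussian quantity) before exponentiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._util import derive_seed

CENSORED = float("inf")   # Cp marker for "no amplification"


@dataclass
class QPCRMeasurement:
    strain: str
    target_gene: str
    reference_gene: str
    efficiency: float
    cp_reference: list[float] = field(default_factory=list)   # replicates
    cp_target: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must lie in (1, 2]")
        if any(c <= 0 for c in self.cp_reference + self.cp_target
               if not math.isinf(c)):
            raise ValueError("Cp values must be positive")


def relative_amplification(efficiency: float, cp_ref, cp_test) -> float:
    """E^(mean Cp_ref) / E^(mean Cp_test); scalar or replicate-list inputs.

    Returns inf when the test gene never amplifies (censored Cp); the
    caller decides how to report "no amplification"."""
    if efficiency <= 1.0:
        raise ValueError("efficiency must exceed 1")
    cp_ref = float(np.mean(np.atleast_1d(cp_ref)))
    cp_test = float(np.mean(np.atleast_1d(cp_test)))
    if math.isinf(cp_test):
        return 0.0
    if math.isinf(cp_ref):
        return CENSORED
    return efficiency ** cp_ref / efficiency ** cp_test


def simulate_cp(template_copies: float, efficiency: float, cp_single_copy: float,
                noise_sd: float, seed: int, n_replicates: int = 1) -> list[float]:
    """Cp = cp_single_copy - log(copies)/log(E) + Gaussian noise; zero
    copies yields the censored marker (no amplification)."""
    if template_copies < 0:
        raise ValueError("template_copies must be >= 0")
    if template_copies == 0:
        return [CENSORED] * n_replicates
    rng = np.random.default_rng(derive_seed(seed, "qpcr_cp"))
    base = cp_single_copy - math.log(template_copies) / math.log(efficiency)
    return [float(base + rng.normal(0.0, noise_sd)) for _ in range(n_replicates)]


@dataclass
class FoldChange:
    fold: float                     # ratio_a / ratio_b; inf/0 when censored
    ci_low: float
    ci_high: float
    censored: bool = False

    def describe(self) -> str:
        if self.censored:
            return "no amplification in one strain"
        return f"{self.fold:.2f} [{self.ci_low:.2f}, {self.ci_high:.2f}]"


def strain_fold_change(meas_a: QPCRMeasurement, meas_b: QPCRMeasurement) -> FoldChange:
    """Within-gene, across-strain fold of relative amplification, with a
    confidence interval from replicate spread (delta Cp scale, +/- 2 SE)."""
    if meas_a.target_gene != meas_b.target_gene or \
            meas_a.reference_gene != meas_b.reference_gene:
        raise ValueError("fold change requires the same target and reference genes")
    if abs(meas_a.efficiency - meas_b.efficiency) > 1e-9:
        raise ValueError("fold change requires a common efficiency")
    E = meas_a.efficiency
    ra = relative_amplification(E, meas_a.cp_reference, meas_a.cp_target)
    rb = relative_amplification(E, meas_b.cp_reference, meas_b.cp_target)
    if ra in (0.0, CENSORED) or rb in (0.0, CENSORED):
        fold = CENSORED if rb in (0.0,) or ra == CENSORED else 0.0
        return FoldChange(fold, fold, fold, censored=True)
    # delta-delta-Cp spread across replicates
    dd = math.log(ra / rb) / math.log(E)
    var = 0.0
    for m in (meas_a, meas_b):
        for reps in (m.cp_reference, m.cp_target):
            reps = np.asarray(reps, dtype=float)
            if len(reps) > 1:
                var += reps.var(ddof=1) / len(reps)
    se = math.sqrt(var)
    return FoldChange(fold=E ** dd, ci_low=E ** (dd - 2 * se), ci_high=E ** (dd + 2 * se))
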