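"""Bidirectional transwell transport analytics.

Apparent permeability of a monolayer is the receiver-side appearance rate
normalized by insert area and donor concentration:

    Papp = (dQ/dt) / (A * C0)        [cm/s]

with dQ/dt in umol/s, A in cm^2 and C0 in umol/cm^3. The efflux ratio
ratio_p = Papp(B->A) / Papp(A->B) classifies the transport mechanism:
values near 1 indicate passive diffusion, large values implicate apically
directed efflux, small values preferential absorptive transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import DirectionDiff, Mechanism, StudyDataset

#: Mechanism bands on ratio_p: passive is the closed interval [0.8, 1.5];
#: efflux requires ratio_p > 2.0; preferential absorptive ratio_p <= 0.5
#: (the study groups a compound printed at exactly 0.50 with this class).
PASSIVE_BAND = (0.8, 1.5)
EFFLUX_CUTOFF = 2.0
ABSORPTIVE_CUTOFF = 0.5


@dataclass(frozen=True)
class TransportAssay:
    """One transwell measurement: appearance rate in the receiver chamber.

    Attributes
    ----------
    rate : float
        Receiver-side appearance rate dQ/dt, umol/s.
    area : float
        Insert membrane area, cm^2.
    c0 : float
        Initial donor concentration, umol/cm^3 (40 uM = 0.04 umol/cm^3).
    duration : float
        Incubation time, minutes.
    direction : str
        "AtoB" (apical to basolateral) or "BtoA".
    """

    rate: float
    area: float
    c0: float
    duration: float = 60.0
    direction: str = "AtoB"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("insert area must be positive")
        if self.c0 <= 0:
            raise ValueError("donor concentration must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.direction not in ("AtoB", "BtoA"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation between permeability and cellular accumulation."""

    n: int
    r: float
    r_squared: float


def compute_papp(assay: TransportAssay) -> float:
    """Apparent permeability (cm/s) of one assay: rate / (area * c0)."""
    return assay.rate / (assay.area * assay.c0)


def efflux_ratio(papp_ab: float, papp_ba: float) -> float:
    """ratio_p = Papp(B->A) / Papp(A->B)."""
    if papp_ab <= 0:
        raise ValueError(f"papp_ab must be > 0, got {papp_ab}")
    return papp_ba / papp_ab


def classify_transport(ratio_p: float) -> Mechanism:
    """Map an efflux ratio to a transport-mechanism class.

    <= 0.5 -> preferential_absorptive; [0.8, 1.5] -> passive;
    > 2.0 -> efflux_implicated; the unnamed gaps (0.5, 0.8) and
    (1.5, 2.0] -> indeterminate.
    """
    if ratio_p <= 0:
        raise ValueError(f"ratio_p must be > 0, got {ratio_p}")
    if ratio_p <= ABSORPTIVE_CUTOFF:
        return Mechanism.PREFERENTIAL_ABSORPTIVE
    if PASSIVE_BAND[0] <= ratio_p <= PASSIVE_BAND[1]:
        return Mechanism.PASSIVE
    if ratio_p > EFFLUX_CUTOFF:
        return Mechanism.EFFLUX_IMPLICATED
    return Mechanism.INDETERMINATE


def accumulation_ratio(ca_ab: float | None, ca_ba: float | None) -> float | None:
    """ratio_c = CA(B->A) / CA(A->B); missing propagates to missing."""
    if ca_ab is None or ca_ba is None:
        return None
    if ca_ab <= 0:
        raise ValueError(f"ca_ab must be > 0, got {ca_ab}")
    return ca_ba / ca_ab


def normalize_ca(amount: float, protein: float) -> float:
    """Cellular accumulation: compound amount (umol) per protein mass (g)."""
    if protein <= 0:
        raise ValueError(f"protein mass must be > 0, got {protein}")
    return amount / protein


class InsufficientDataError(ValueError):
    """Raised when too few complete observations remain for a statistic."""


def correlate_papp_ca(dataset: StudyDataset, direction: str = "AtoB") -> CorrelationReport:
    """Pearson correlation between Papp and cellular accumulation.

    Uses compounds for which the accumulation in the requested direction is
    not missing (ND/NT rows are excluded, never zero-filled).
    """
    if direction not in ("AtoB", "BtoA"):
        raise ValueError(f"unknown direction {direction!r}")
    papp_attr = "papp_ab" if direction == "AtoB" else "papp_ba"
    ca_attr = "ca_ab" if direction == "AtoB" else "ca_ba"
    pairs = [
        (getattr(dataset.transport[cid], papp_attr), getattr(acc, ca_attr))
        for cid, acc in dataset.accumulation.items()
        if getattr(acc, ca_attr) is not None and cid in dataset.transport
    ]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 complete (Papp, CA) pairs for {direction}, have {len(pairs)}"
        )
    x, y = np.asarray(pairs, dtype=float).T
    r = stats.pearsonr(x, y).statistic
    return CorrelationReport(n=len(pairs), r=float(r), r_squared=float(r) ** 2)


def compare_ca_directions(
    reps_ab, reps_ba, alpha_levels: tuple[float, float] = (0.05, 0.01)
) -> DirectionDiff:
    """Flag the A->B vs B->A accumulation difference with a pooled-variance t-test.

    Two-sided two-sample Student's t-test (equal-variance form). Returns
    ``unevaluable`` when either side has fewer than two replicates.
    """
    reps_ab = np.asarray(reps_ab, dtype=float)
    reps_ba = np.asarray(reps_ba, dtype=float)
    if reps_ab.size < 2 or reps_ba.size < 2:
        return DirectionDiff.UNEVALUABLE
    result = stats.ttest_ind(reps_ab, reps_ba, equal_var=True)
    p = float(result.pvalue)
    if np.isnan(p):  # zero variance on both sides with equal means
        p = 1.0
    weak, strong = max(alpha_levels), min(alpha_levels)
    if p < strong:
        return DirectionDiff.P01
    if p < weak:
        return DirectionDiff.P05
    return DirectionDiff.NS


def transport_report(dataset: StudyDataset):
    """Per-compound transport summary table (Papp on the 1e-6 cm/s scale)."""
    import pandas as pd

    rows = []
    for cid in sorted(dataset.transport):
        t = dataset.transport[cid]
        a = dataset.accumulation.get(cid)
        rows.append(
            {
                "id": cid,
                "papp_ab": t.papp_ab / 1e-6,
                "papp_ba": t.papp_ba / 1e-6,
                "ratio_p": t.ratio_p,
                "mechanism": t.mechanism.value,
                "ca_ab": a.ca_ab if a else None,
                "ca_ba": a.ca_ba if a else None,
                "ratio_c": a.ratio_c if a else None,
                "direction_diff": a.direction_diff.value if a else None,
            }
        )
    return pd.DataFrame(rows)
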