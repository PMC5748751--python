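"""Solvent-stability and monolayer quality-control checks.

Compound stability in the transport buffer is expressed as the relative
concentration against methanol (peak-area ratio, percent); mass balance of
an assay is the recovered fraction of the dose summed over both chambers
and the cell monolayer. Monolayers qualify for transport work only with a
trans-epithelial electrical resistance above 600 Ohm*cm^2 and a Lucifer
yellow paracellular flux below 0.5e-6 cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import StabilityClass

STABLE_CUTOFF = 50.0
UNSTABLE_CUTOFF = 40.0
TEER_GATE = 600.0          # Ohm*cm^2, exclusive lower bound
LY_PAPP_GATE = 0.5e-6      # cm/s, exclusive upper bound
RECOVERY_GATE = 60.0       # percent, configurable acceptance threshold


@dataclass(frozen=True)
class MonolayerQc:
    """Integrity readouts of one monolayer."""

    teer: float
    ly_papp: float

    def __post_init__(self) -> None:
        if self.teer < 0 or self.ly_papp < 0:
            raise ValueError("TEER and Lucifer yellow Papp must be >= 0")


@dataclass(frozen=True)
class QcVerdict:
    passed: bool
    reasons: tuple[str, ...]


def relative_concentration(peak_dhanks: float, peak_methanol: float) -> float:
    """Relative concentration (%) = 100 * peak(D-Hank's) / peak(methanol).

    Values above 100% are legal (solubility in the buffer can exceed the
    methanol reference).
    """
    if peak_methanol <= 0:
        raise ValueError(f"methanol peak area must be > 0, got {peak_methanol}")
    return 100.0 * peak_dhanks / peak_methanol


def classify_stability(rel_conc: float) -> StabilityClass:
    """>= 50% stable, < 40% unstable, the unnamed gap [40, 50) questionable."""
    if rel_conc < 0:
        raise ValueError(f"relative concentration must be >= 0, got {rel_conc}")
    if rel_conc >= STABLE_CUTOFF:
        return StabilityClass.STABLE
    if rel_conc < UNSTABLE_CUTOFF:
        return StabilityClass.UNSTABLE
    return StabilityClass.QUESTIONABLE


def mass_balance_recovery(
    receiver_amount: float,
    donor_amount: float,
    cellular_amount: float,
    dosed_amount: float,
) -> float:
    """Recovery (%) of the dose over receiver + donor + cell compartments."""
    if dosed_amount <= 0:
        raise ValueError(f"dosed amount must be > 0, got {dosed_amount}")
    amounts = (receiver_amount, donor_amount, cellular_amount)
    if any(a < 0 for a in amounts):
        raise ValueError("compartment amounts must be >= 0")
    return 100.0 * sum(amounts) / dosed_amount


def rsd(mean: float, sd: float) -> float:
    """Relative standard deviation (%) = 100 * SD / mean."""
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    return 100.0 * sd / mean


def qc_monolayer(qc: MonolayerQc) -> QcVerdict:
    """Pass iff TEER > 600 Ohm*cm^2 and Lucifer yellow Papp < 0.5e-6 cm/s.

    Both bounds are exclusive; a failing verdict lists every violated gate.
    """
    reasons = []
    if not qc.teer > TEER_GATE:
        reasons.append(f"TEER {qc.teer:g} Ohm*cm^2 not above {TEER_GATE:g}")
    if not qc.ly_papp < LY_PAPP_GATE:
        reasons.append(
            f"Lucifer yellow Papp {qc.ly_papp:g} cm/s not below {LY_PAPP_GATE:g}"
        )
    return QcVerdict(passed=not reasons, reasons=tuple(reasons))
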