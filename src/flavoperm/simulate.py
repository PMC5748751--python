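"""Synthetic data with the statistical structure the analysis assumes.

Two generators cover the two experimental layers:

* :func:`gen_qspr_dataset` draws correlated Gaussian descriptors and a
  linear pPapp response with additive Gaussian noise — the structure the
  QSPR engine assumes. Defaults put the synthetic compounds on the scale of
  the real study: descriptor marginals and inter-correlations equal the
  empirical values of the 28 modelled flavonoids, the true coefficients are
  the published model weights, and the noise SD equals the published
  training RMSE (0.141 log units).
* :func:`gen_transport_experiment` emulates a bidirectional transwell assay
  under sink conditions: receiver appearance rates are linear in Papp with
  multiplicative Gaussian noise (chromatographic quantification error
  scales with signal), the secretory direction scaled by a true efflux
  ratio.

All generators are pure functions of their spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import DESCRIPTOR_NAMES
from .transport import TransportAssay

#: Published model weights used as generating truth by default.
DEFAULT_INTERCEPT = 4.715
DEFAULT_COEFFICIENTS = {
    "QC3p": 1.358,
    "E_sol": 0.059,
    "SlogP_V3": 0.020,
    "vsurf_ID1": 0.056,
}
#: Noise SD on the pPapp scale; equals the study's training RMSE.
DEFAULT_NOISE_SD = 0.141

DEFAULT_SEED = 20171129


def _study_descriptor_moments() -> tuple[dict, dict, np.ndarray]:
    """Empirical means/SDs and inter-correlation of the study descriptors."""
    from .io import descriptor_frame, load_dataset

    frame = descriptor_frame(load_dataset("fang2017"))
    means = frame.mean().to_dict()
    sds = frame.std(ddof=1).to_dict()
    return means, sds, frame.corr().to_numpy()


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic QSPR dataset.

    ``descriptor_correlation`` must be symmetric positive definite; the
    train/test split sizes default to the study's 22/6.
    """

    n_compounds: int = 28
    n_train: int | None = None
    descriptor_names: tuple = DESCRIPTOR_NAMES
    descriptor_means: dict = field(default_factory=dict)
    descriptor_sds: dict = field(default_factory=dict)
    descriptor_correlation: np.ndarray | None = None
    true_intercept: float = DEFAULT_INTERCEPT
    true_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_compounds < 4:
            raise ValueError("need at least 4 synthetic compounds")
        if self.n_train is None:
            # keep the study's 22/6 train/test proportion
            self.n_train = self.n_compounds - max(1, round(self.n_compounds * 6 / 28))
        if not 0 < self.n_train <= self.n_compounds:
            raise ValueError("n_train must be in (0, n_compounds]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.descriptor_means or not self.descriptor_sds:
            means, sds, corr = _study_descriptor_moments()
            self.descriptor_means = self.descriptor_means or means
            self.descriptor_sds = self.descriptor_sds or sds
            if self.descriptor_correlation is None:
                self.descriptor_correlation = corr
        k = len(self.descriptor_names)
        if self.descriptor_correlation is None:
            self.descriptor_correlation = np.eye(k)
        corr = np.asarray(self.descriptor_correlation, dtype=float)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("descriptor_correlation must be a symmetric k x k matrix")
        self.descriptor_correlation = corr


def gen_qspr_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw a synthetic descriptor table with linear pPapp response.

    Returns a DataFrame indexed by compound id (1..n) with the descriptor
    columns, ``ppapp_exp`` and a ``split`` column ("training"/"test"
    assigned at random, sizes ``n_train`` / rest).

    Raises
    ------
    ValueError
        If the requested correlation matrix is not positive definite.
    """
    names = list(spec.descriptor_names)
    sds = np.array([spec.descriptor_sds[n] for n in names], dtype=float)
    means = np.array([spec.descriptor_means[n] for n in names], dtype=float)
    cov = spec.descriptor_correlation * np.outer(sds, sds)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("descriptor correlation matrix is not positive definite") from exc

    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_compounds, len(names)))
    X = means + z @ chol.T
    beta = np.array([spec.true_coefficients[n] for n in names], dtype=float)
    y = spec.true_intercept + X @ beta
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)

    split = np.full(spec.n_compounds, "test", dtype=object)
    train_rows = rng.permutation(spec.n_compounds)[: spec.n_train]
    split[train_rows] = "training"

    frame = pd.DataFrame(X, columns=names, index=pd.RangeIndex(1, spec.n_compounds + 1, name="id"))
    frame["ppapp_exp"] = y
    frame["split"] = split
    return frame


def gen_transport_experiment(
    papp_true_ab: float,
    ratio_p_true: float,
    area: float = 1.13,
    c0: float = 0.04,
    duration: float = 60.0,
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = DEFAULT_SEED,
    donor_volume_ab: float = 0.4,
    donor_volume_ba: float = 1.95,
    sink_fraction: float = 0.10,
) -> dict[str, list[TransportAssay]]:
    """Simulate replicate bidirectional transwell assays.

    The noise-free receiver appearance rate is ``Papp * area * c0`` per
    direction (B->A uses ``papp_true_ab * ratio_p_true``); each replicate
    perturbs it with multiplicative Gaussian noise of coefficient of
    variation ``cv``. Default geometry matches a 12-well hanging insert
    (1.13 cm^2, apical volume 0.4 cm^3, basolateral 1.95 cm^3) with a 40 uM
    dose over 60 min.

    Raises
    ------
    ValueError
        If the noise-free transported amount would exceed ``sink_fraction``
        of the donor dose in either direction (sink-condition violation);
        the message advises a shorter duration.
    """
    if min(papp_true_ab, ratio_p_true, area, c0, duration, n_replicates) <= 0:
        raise ValueError("all assay parameters must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    seconds = duration * 60.0
    papp = {"AtoB": papp_true_ab, "BtoA": papp_true_ab * ratio_p_true}
    volume = {"AtoB": donor_volume_ab, "BtoA": donor_volume_ba}
    for direction in ("AtoB", "BtoA"):
        transported_fraction = papp[direction] * area * seconds / volume[direction]
        if transported_fraction >= sink_fraction:
            raise ValueError(
                f"{direction}: {100 * transported_fraction:.1f}% of the dose would "
                f"cross the monolayer, violating the {100 * sink_fraction:.0f}% sink "
                f"condition; use a shorter duration or lower Papp"
            )
    rng = np.random.default_rng(seed)
    out: dict[str, list[TransportAssay]] = {}
    for direction in ("AtoB", "BtoA"):
        true_rate = papp[direction] * area * c0
        noise = rng.normal(0.0, cv, size=n_replicates) if cv > 0 else np.zeros(n_replicates)
        out[direction] = [
            TransportAssay(
                rate=float(true_rate * (1.0 + e)),
                area=area,
                c0=c0,
                duration=duration,
                direction=direction,
            )
            for e in noise
        ]
    return out
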