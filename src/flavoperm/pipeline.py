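"""End-to-end analysis pipeline and report generation.

``run_pipeline`` ties the stages together on one dataset: transport and
stability reports, the descriptor correlation matrix, collinearity filter,
stepwise selection, model fit with leave-one-out cross-validation, external
validation on the test split, and per-compound predictions. Outputs are
deterministic for a given configuration and seed; nothing is written until
every stage has succeeded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io import descriptor_frame, load_dataset, response_series
from .qspr import (
    QsprRegressor,
    correlation_matrix,
    filter_collinear,
    loo_q2,
    stepwise_select,
    validate_external,
)
from .records import StudyDataset
from .transport import transport_report


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults are the study settings)."""

    source: str = "fang2017"
    out_dir: str = "flavoperm_out"
    collinearity_threshold: float = 0.7
    enter_p: float = 0.05
    remove_p: float = 0.10
    outlier_threshold: float = 0.600
    method: str = "ols"
    n_components: int | None = None
    seed: int = 20171129

    def __post_init__(self) -> None:
        for name in ("collinearity_threshold", "enter_p", "remove_p", "outlier_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    config: RunConfig
    dataset: StudyDataset
    transport: pd.DataFrame
    stability: pd.DataFrame
    correlation: pd.DataFrame
    selected: list[str]
    model_json: str
    qspr_table: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)

    def write(self) -> Path:
        out = Path(self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = lambda frame: frame.to_csv(index=False, float_format="%.6g")
        (out / "transport_report.csv").write_text(fmt(self.transport))
        (out / "stability_report.csv").write_text(fmt(self.stability))
        (out / "correlation_matrix.csv").write_text(
            self.correlation.to_csv(float_format="%.6g")
        )
        (out / "qspr_report.csv").write_text(fmt(self.qspr_table))
        (out / "qspr_model.json").write_text(self.model_json)
        (out / "run.log").write_text("\n".join(self.log_lines) + "\n")
        return out


def _stability_table(ds: StudyDataset) -> pd.DataFrame:
    rows = []
    for cid in sorted(ds.stability):
        s = ds.stability[cid]
        rows.append(
            {
                "id": cid,
                "relative_concentration": s.relative_concentration,
                "stability_class": s.stability_class.value,
                "recovery_ab": s.recovery_ab,
                "rsd_ab": s.rsd_ab,
                "recovery_ba": s.recovery_ba,
                "rsd_ba": s.rsd_ba,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every analysis stage on the configured dataset and return reports."""
    log = [
        f"flavoperm {__version__}",
        f"config {config.digest()}",
        f"seed {config.seed}",
    ]

    try:
        ds = load_dataset(config.source)
    except Exception as exc:
        raise PipelineError("load", exc)

    try:
        transport = transport_report(ds)
        efflux = transport.loc[transport.mechanism == "efflux_implicated", "id"].tolist()
        log.append(f"transport: {len(transport)} compounds, efflux-implicated {efflux}")
    except Exception as exc:
        raise PipelineError("transport", exc)

    stability = _stability_table(ds)
    log.append(f"stability: {len(stability)} compounds with QC data")

    try:
        X = descriptor_frame(ds, split="training")
        y = response_series(ds, split="training")
        corr = correlation_matrix(y, X, response_name="ppapp_exp")
        retained, dropped = filter_collinear(corr, config.collinearity_threshold)
        log.append(
            f"collinearity: retained {retained}"
            + (f", dropped {dropped}" if dropped else "")
        )
        selected = stepwise_select(
            X[retained], y, enter_p=config.enter_p, remove_p=config.remove_p
        )
        log.append(f"stepwise: selected {selected}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("screening", exc)

    try:
        est = QsprRegressor(method=config.method, n_components=config.n_components)
        est.fit(X[selected], y)
        q2, press = loo_q2(X[selected], y, method=config.method,
                           n_components=config.n_components)
        X_test = descriptor_frame(ds, split="test")[selected]
        y_test = response_series(ds, split="test")
        r2_pred, rmse_test = validate_external(est, X_test, y_test, float(y.mean()))
        model = est.to_model(training_ids=list(X.index))
        stats = est.stats(q2=q2, press=press, r2_pred=r2_pred, ids=list(X.index))
        log.append(
            "fit: R2 = {r2:.3f} (coefficient of determination), "
            "R2_adj = {r2_adj:.3f}, F = {f:.3f}, SEE = {see:.3f}, "
            "RMSE = {rmse:.3f} (root-mean-square error), "
            "Q2 = {q2:.3f} (leave-one-out), PRESS = {press:.3f}, "
            "R2_pred = {r2p:.3f} (test set, train-mean reference), "
            "test RMSE = {rmset:.3f}".format(
                r2=stats.r2, r2_adj=stats.r2_adj, f=stats.f_stat, see=stats.see,
                rmse=stats.rmse, q2=q2, press=press, r2p=r2_pred, rmset=rmse_test,
            )
        )
        model_json = model.to_json(stats)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit", exc)

    try:
        rows = []
        for split in ("training", "test"):
            Xs = descriptor_frame(ds, split=split)
            ys = response_series(ds, split=split)
            pred = est.predict(Xs[selected])
            for cid, yhat in zip(Xs.index, pred):
                rows.append(
                    {
                        "id": cid,
                        "split": split,
                        "ppapp_exp": ys[cid],
                        "ppapp_pred": float(yhat),
                        "residual": float(ys[cid] - yhat),
                        **{n: Xs.loc[cid, n] for n in Xs.columns},
                    }
                )
        qspr_table = pd.DataFrame(rows)
    except Exception as exc:
        raise PipelineError("report", exc)

    return ReportBundle(
        config=config,
        dataset=ds,
        transport=transport,
        stability=stability,
        correlation=corr.to_frame().round(6),
        selected=selected,
        model_json=model_json,
        qspr_table=qspr_table,
        log_lines=log,
    )
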