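"""Reading and writing study datasets.

A dataset on disk is a directory of up to five UTF-8, comma-separated files
(``compounds.csv``, ``transport.csv``, ``accumulation.csv``, ``stability.csv``,
``descriptors.csv``) sharing a compound ``id`` key. ``load_dataset`` also
accepts the name of a packaged fixture (currently ``"fang2017"``, the 30
flavonoid study tables).

Conventions:

* Papp columns in ``transport.csv`` are on the 1e-6 cm/s display scale;
  in-memory values are plain cm/s.
* ``ND`` (not detected), ``NT`` (not tested) and ``-`` (not available) are
  missing-value literals; they are preserved as missing, never as zero.
  Any other non-numeric cell is an error.
"""

from __future__ import annotations

import importlib.resources
import json
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .records import (
    DESCRIPTOR_NAMES,
    MISSING_CODES,
    POSITIONS,
    AccumulationResult,
    CompoundRecord,
    DescriptorSet,
    DirectionDiff,
    Mechanism,
    PermeabilityObservation,
    Split,
    StabilityClass,
    StabilityRecord,
    StudyDataset,
    Subclass,
    TransportResult,
)
from .stability import classify_stability
from .transport import classify_transport

PAPP_DISPLAY_SCALE = 1e-6

_SCHEMAS = {
    "compounds": ["id", "name", "subclass", *POSITIONS, "is_glycoside"],
    "transport": [
        "id",
        "papp_ab_mean",
        "papp_ab_sd",
        "papp_ba_mean",
        "papp_ba_sd",
    ],
    "accumulation": ["id", "ca_ab_mean", "ca_ab_sd", "ca_ba_mean", "ca_ba_sd"],
    "stability": ["id", "relative_concentration"],
    "descriptors": ["id", "ppapp_exp", "split", *DESCRIPTOR_NAMES],
}


class DatasetFormatError(ValueError):
    """Raised for malformed dataset files (header, cells, duplicate keys)."""


def _fixture_dir() -> Path:
    return Path(importlib.resources.files("flavoperm.datasets") / "data")


def _read_table(path: Path, kind: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{kind} table not found: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise DatasetFormatError(f"{path}: malformed header (empty file)") from exc
    required = _SCHEMAS[kind]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"{path}: malformed header, missing columns {missing}")
    ids = pd.to_numeric(frame["id"], errors="coerce")
    if ids.isna().any():
        raise DatasetFormatError(f"{path}: non-integer compound id")
    frame["id"] = ids.astype(int)
    if frame["id"].duplicated().any():
        dupes = sorted(frame.loc[frame["id"].duplicated(), "id"].unique().tolist())
        raise DatasetFormatError(f"{path}: duplicate compound_id {dupes}")
    return frame


def _cell(raw: str, *, where: str) -> float | None:
    """Parse one numeric cell; missing literals map to None."""
    text = raw.strip()
    if text in MISSING_CODES or text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise DatasetFormatError(f"{where}: non-numeric cell {raw!r}") from exc


def _load_compounds(path: Path) -> dict[int, CompoundRecord]:
    frame = _read_table(path, "compounds")
    out: dict[int, CompoundRecord] = {}
    for row in frame.itertuples(index=False):
        cid = int(row.id)
        out[cid] = CompoundRecord(
            compound_id=cid,
            name=row.name,
            subclass=Subclass(row.subclass),
            substituents={p: getattr(row, p) for p in POSITIONS},
            is_glycoside=str(row.is_glycoside).lower() in {"true", "1", "yes"},
        )
    return out


def _load_transport(path: Path) -> dict[int, TransportResult]:
    from .transport import efflux_ratio

    frame = _read_table(path, "transport")
    out: dict[int, TransportResult] = {}
    for row in frame.itertuples(index=False):
        cid = int(row.id)
        where = f"{path}:compound {cid}"
        ab = _cell(row.papp_ab_mean, where=where)
        ab_sd = _cell(row.papp_ab_sd, where=where)
        ba = _cell(row.papp_ba_mean, where=where)
        ba_sd = _cell(row.papp_ba_sd, where=where)
        if None in (ab, ab_sd, ba, ba_sd):
            raise DatasetFormatError(f"{where}: transport values may not be missing")
        ab, ab_sd, ba, ba_sd = (v * PAPP_DISPLAY_SCALE for v in (ab, ab_sd, ba, ba_sd))
        ratio = efflux_ratio(ab, ba)
        printed = None
        if "ratio_p_printed" in frame.columns:
            printed = _cell(getattr(row, "ratio_p_printed"), where=where)
        out[cid] = TransportResult(
            compound_id=cid,
            papp_ab=ab,
            papp_ab_sd=ab_sd,
            papp_ba=ba,
            papp_ba_sd=ba_sd,
            ratio_p=ratio,
            mechanism=classify_transport(ratio),
            ratio_p_printed=printed,
        )
    return out


def _load_accumulation(path: Path) -> dict[int, AccumulationResult]:
    from .transport import accumulation_ratio

    frame = _read_table(path, "accumulation")
    out: dict[int, AccumulationResult] = {}
    for row in frame.itertuples(index=False):
        cid = int(row.id)
        where = f"{path}:compound {cid}"
        ab = _cell(row.ca_ab_mean, where=where)
        ab_sd = _cell(row.ca_ab_sd, where=where)
        ba = _cell(row.ca_ba_mean, where=where)
        ba_sd = _cell(row.ca_ba_sd, where=where)
        code = row.ca_ab_mean.strip() if ab is None else None
        ratio = accumulation_ratio(ab, ba) if ab is not None and ba is not None else None
        printed = None
        if "ratio_c_printed" in frame.columns:
            printed = _cell(getattr(row, "ratio_c_printed"), where=where)
        if "direction_diff" in frame.columns:
            diff = DirectionDiff(getattr(row, "direction_diff"))
        else:
            diff = DirectionDiff.UNEVALUABLE
        out[cid] = AccumulationResult(
            compound_id=cid,
            ca_ab=ab,
            ca_ab_sd=ab_sd,
            ca_ba=ba,
            ca_ba_sd=ba_sd,
            ratio_c=ratio,
            direction_diff=diff,
            missing_code=code,
            ratio_c_printed=printed,
        )
    return out


def _load_stability(path: Path) -> dict[int, StabilityRecord]:
    frame = _read_table(path, "stability")
    out: dict[int, StabilityRecord] = {}
    opt = [
        "recovery_ab_mean",
        "recovery_ab_sd",
        "rsd_ab",
        "recovery_ba_mean",
        "recovery_ba_sd",
        "rsd_ba",
    ]
    for row in frame.itertuples(index=False):
        cid = int(row.id)
        where = f"{path}:compound {cid}"
        rel = _cell(row.relative_concentration, where=where)
        extra = {
            c: (_cell(getattr(row, c), where=where) if c in frame.columns else None)
            for c in opt
        }
        out[cid] = StabilityRecord(
            compound_id=cid,
            relative_concentration=rel,
            recovery_ab=extra["recovery_ab_mean"],
            recovery_ab_sd=extra["recovery_ab_sd"],
            rsd_ab=extra["rsd_ab"],
            recovery_ba=extra["recovery_ba_mean"],
            recovery_ba_sd=extra["recovery_ba_sd"],
            rsd_ba=extra["rsd_ba"],
            stability_class=(
                classify_stability(rel) if rel is not None else StabilityClass.UNKNOWN
            ),
        )
    return out


def _load_descriptors(
    path: Path,
) -> tuple[dict[int, DescriptorSet], dict[int, PermeabilityObservation]]:
    frame = _read_table(path, "descriptors")
    desc: dict[int, DescriptorSet] = {}
    obs: dict[int, PermeabilityObservation] = {}
    for row in frame.itertuples(index=False):
        cid = int(row.id)
        where = f"{path}:compound {cid}"
        values = {name: _cell(getattr(row, name), where=where) for name in DESCRIPTOR_NAMES}
        if any(v is None for v in values.values()):
            raise DatasetFormatError(f"{where}: descriptor values may not be missing")
        desc[cid] = DescriptorSet(compound_id=cid, values=values)
        pred = None
        if "ppapp_pred" in frame.columns:
            pred = _cell(getattr(row, "ppapp_pred"), where=where)
        obs[cid] = PermeabilityObservation(
            compound_id=cid,
            ppapp_exp=float(row.ppapp_exp),
            split=Split(row.split),
            ppapp_pred_printed=pred,
        )
    return desc, obs


def load_dataset(source: str | Path) -> StudyDataset:
    """Load a study dataset from a directory of CSVs or a packaged fixture.

    Parameters
    ----------
    source
        Either the name of a packaged fixture (``"fang2017"``) or a path to
        a directory containing the documented CSV files. ``compounds.csv``
        and ``transport.csv`` are required; the other tables are optional.

    Returns
    -------
    StudyDataset
        Fully cross-linked dataset. Rows referencing a compound id absent
        from ``compounds.csv`` raise ``ValueError``.
    """
    if isinstance(source, str) and source == "fang2017":
        root = _fixture_dir()
    else:
        root = Path(source)
        if not root.exists():
            raise FileNotFoundError(f"dataset directory not found: {root}")

    ds = StudyDataset()
    ds.compounds = _load_compounds(root / "compounds.csv")
    ds.transport = _load_transport(root / "transport.csv")
    for name, loader in (
        ("accumulation", _load_accumulation),
        ("stability", _load_stability),
    ):
        path = root / f"{name}.csv"
        if path.exists():
            setattr(ds, name, loader(path))
    path = root / "descriptors.csv"
    if path.exists():
        ds.descriptors, ds.observations = _load_descriptors(path)
    ds.validate_links()
    return ds


def descriptor_frame(ds: StudyDataset, split: str | None = None) -> pd.DataFrame:
    """Descriptor matrix (rows indexed by compound id, canonical column order)."""
    ids: Iterable[int]
    if split is None:
        ids = sorted(ds.descriptors)
    else:
        ids = [i for i in sorted(ds.descriptors) if ds.observations[i].split == Split(split)]
    return pd.DataFrame(
        [[ds.descriptors[i].values[n] for n in DESCRIPTOR_NAMES] for i in ids],
        index=pd.Index(ids, name="id"),
        columns=list(DESCRIPTOR_NAMES),
    )


def response_series(ds: StudyDataset, split: str | None = None) -> pd.Series:
    """Experimental pPapp response aligned with :func:`descriptor_frame`."""
    frame = descriptor_frame(ds, split)
    return pd.Series(
        [ds.observations[i].ppapp_exp for i in frame.index],
        index=frame.index,
        name="ppapp_exp",
    )


def write_dataset(ds: StudyDataset, outdir: str | Path) -> None:
    """Write a dataset back to the documented CSV schemas (round-trippable)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def fmt(v: float | None, code: str | None = None, nd: int = 6) -> str:
        if v is None:
            return code or "-"
        return f"{v:.{nd}g}"

    rows = [
        {
            "id": c.compound_id,
            "name": c.name,
            "subclass": c.subclass.value,
            **{p: c.substituents[p] for p in POSITIONS},
            "is_glycoside": str(c.is_glycoside).lower(),
        }
        for c in ds.compounds.values()
    ]
    pd.DataFrame(rows).to_csv(outdir / "compounds.csv", index=False)

    rows = [
        {
            "id": t.compound_id,
            "papp_ab_mean": fmt(t.papp_ab / PAPP_DISPLAY_SCALE),
            "papp_ab_sd": fmt(t.papp_ab_sd / PAPP_DISPLAY_SCALE),
            "papp_ba_mean": fmt(t.papp_ba / PAPP_DISPLAY_SCALE),
            "papp_ba_sd": fmt(t.papp_ba_sd / PAPP_DISPLAY_SCALE),
            "ratio_p_printed": fmt(t.ratio_p_printed),
        }
        for t in ds.transport.values()
    ]
    pd.DataFrame(rows).to_csv(outdir / "transport.csv", index=False)

    if ds.accumulation:
        rows = [
            {
                "id": a.compound_id,
                "ca_ab_mean": fmt(a.ca_ab, a.missing_code),
                "ca_ab_sd": fmt(a.ca_ab_sd, a.missing_code),
                "ca_ba_mean": fmt(a.ca_ba, a.missing_code),
                "ca_ba_sd": fmt(a.ca_ba_sd, a.missing_code),
                "ratio_c_printed": fmt(a.ratio_c_printed),
                "direction_diff": a.direction_diff.value,
            }
            for a in ds.accumulation.values()
        ]
        pd.DataFrame(rows).to_csv(outdir / "accumulation.csv", index=False)

    if ds.stability:
        rows = [
            {
                "id": s.compound_id,
                "relative_concentration": fmt(
                    s.relative_concentration,
                    "ND" if s.relative_concentration is None else None,
                ),
                "recovery_ba_mean": fmt(s.recovery_ba),
                "recovery_ba_sd": fmt(s.recovery_ba_sd),
                "rsd_ba": fmt(s.rsd_ba),
                "recovery_ab_mean": fmt(s.recovery_ab),
                "recovery_ab_sd": fmt(s.recovery_ab_sd),
                "rsd_ab": fmt(s.rsd_ab),
            }
            for s in ds.stability.values()
        ]
        pd.DataFrame(rows).to_csv(outdir / "stability.csv", index=False)

    if ds.descriptors:
        rows = [
            {
                "id": cid,
                "ppapp_exp": fmt(ds.observations[cid].ppapp_exp),
                "ppapp_pred": fmt(ds.observations[cid].ppapp_pred_printed),
                "split": ds.observations[cid].split.value,
                **{n: fmt(ds.descriptors[cid].values[n]) for n in DESCRIPTOR_NAMES},
            }
            for cid in ds.descriptors
        ]
        pd.DataFrame(rows).to_csv(outdir / "descriptors.csv", index=False)


def dataset_to_json(ds: StudyDataset) -> str:
    """Serialize a dataset to a JSON document."""

    def rec(obj) -> dict:
        out = {}
        for key, value in obj.__dict__.items():
            if isinstance(value, Enum):
                value = value.value
            elif isinstance(value, Mapping):
                value = dict(value)
            out[key] = value
        return out

    payload = {
        "compounds": [rec(c) for c in ds.compounds.values()],
        "transport": [rec(t) for t in ds.transport.values()],
        "accumulation": [rec(a) for a in ds.accumulation.values()],
        "stability": [rec(s) for s in ds.stability.values()],
        "descriptors": [
            {"compound_id": d.compound_id, "values": dict(d.values)}
            for d in ds.descriptors.values()
        ],
        "observations": [rec(o) for o in ds.observations.values()],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
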