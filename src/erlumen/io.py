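"""Readers, writers and validation shared by all pipeline stages.

Input tables are comma- or tab-separated UTF-8 with a header and '.'
decimal separator; outputs are tab-separated with a deterministic column
order.  Units are fixed package-wide: uM for [Ca2+], s for time, pA for
current, mV for potential.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_signals import CellRatioTrace
from .counts import CountTable, EnrichmentResult
from .dose_response import HillFit, PoDataset
from .errors import ValidationError
from .gating import CurrentTrace, Ramp

CONDITION_ALIASES = {
    "0": 0,
    "1": 1,
    "control": 0,
    "scrambled": 0,
    "bait": 1,
    "treated": 1,
}


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def _parse_counts(series: pd.Series) -> pd.Series:
    """Counts must be integers; integral floats ('3.0') pass with a warning."""
    values = pd.to_numeric(series, errors="coerce")
    if values.isna().any():
        bad = series[values.isna()].unique()[:5].tolist()
        raise ValidationError(f"non-numeric counts: {bad}")
    frac = values - np.floor(values)
    if (frac != 0).any():
        bad = series[frac != 0].unique()[:5].tolist()
        raise ValidationError(f"non-integer counts: {bad}")
    if not pd.api.types.is_integer_dtype(series):
        warnings.warn("counts given as floats; coercing to integers", stacklevel=2)
    return values.astype(np.int64)


def read_count_table(path: str | Path, impute_missing: bool = False) -> CountTable:
    """Read a long-format spectral-count table.

    Required columns: ``protein_id, block_id, condition, count``; the
    condition accepts {0, 1} or {control/scrambled, bait/treated} labels.
    """
    df = _read_table(path)
    missing = [c for c in ("protein_id", "block_id", "condition", "count") if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    cond = df["condition"].astype(str).str.strip().str.lower()
    unknown = sorted(set(cond.unique()) - set(CONDITION_ALIASES))
    if unknown:
        raise ValidationError(f"unrecognised condition labels: {unknown}")
    df = df.assign(
        condition=cond.map(CONDITION_ALIASES),
        count=_parse_counts(df["count"]),
    )
    return CountTable.from_dataframe(df, impute_missing=impute_missing)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# current traces


REQUIRED_TRACE_META = ("sampling_rate_hz", "filter_cutoff_hz")


def read_trace(path: str | Path, metadata_path: str | Path) -> CurrentTrace:
    """Read a ``time_s,current_pA`` table plus a YAML/JSON sidecar.

    The sidecar must provide ``sampling_rate_hz`` and
    ``filter_cutoff_hz``; it may give a constant ``v_app_mv`` or a
    ``ramp: {start_mv, end_mv, duration_s}`` plus optional
    ``closed_level_pa`` and ``open_increment_pa``.  Sampling must be
    uniform (jitter below 10% of the interval) and time monotone.
    """
    df = _read_table(path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValidationError(f"trace file missing column {col!r}")
    meta_path = Path(metadata_path)
    with open(meta_path, encoding="utf-8") as fh:
        meta = (
            json.load(fh) if meta_path.suffix == ".json" else yaml.safe_load(fh)
        )
    for key in REQUIRED_TRACE_META:
        if key not in meta:
            raise ValidationError(f"trace metadata missing key {key!r}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValidationError("time column must be strictly increasing")
    interval = 1.0 / float(meta["sampling_rate_hz"])
    if np.abs(dt - interval).max() > 0.1 * interval:
        raise ValidationError("non-uniform sampling (jitter above 10% of interval)")
    if "ramp" in meta:
        r = meta["ramp"]
        v_app: float | Ramp = Ramp(
            start_mv=float(r["start_mv"]),
            end_mv=float(r["end_mv"]),
            duration_s=float(r["duration_s"]),
        )
    else:
        v_app = float(meta.get("v_app_mv", 0.0))
    return CurrentTrace(
        samples=df["current_pA"].to_numpy(dtype=float),
        sampling_rate=float(meta["sampling_rate_hz"]),
        filter_cutoff=float(meta["filter_cutoff_hz"]),
        v_app=v_app,
        closed_level=meta.get("closed_level_pa"),
        open_increment=meta.get("open_increment_pa"),
    )


def write_trace(
    trace: CurrentTrace, path: str | Path, metadata_path: str | Path
) -> None:
    df = pd.DataFrame({"time_s": trace.time, "current_pA": trace.samples})
    df.to_csv(path, sep="\t", index=False)
    meta: dict = {
        "sampling_rate_hz": trace.sampling_rate,
        "filter_cutoff_hz": trace.filter_cutoff,
    }
    if isinstance(trace.v_app, Ramp):
        meta["ramp"] = {
            "start_mv": trace.v_app.start_mv,
            "end_mv": trace.v_app.end_mv,
            "duration_s": trace.v_app.duration_s,
        }
    else:
        meta["v_app_mv"] = trace.v_app
    if trace.closed_level is not None:
        meta["closed_level_pa"] = trace.closed_level
    if trace.open_increment is not None:
        meta["open_increment_pa"] = trace.open_increment
    with open(metadata_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# dose-response and cell tables


def read_po_table(path: str | Path) -> PoDataset:
    """Read ``ca_er_uM, mean_po[, sem, n]``."""
    df = _read_table(path)
    for col in ("ca_er_uM", "mean_po"):
        if col not in df.columns:
            raise ValidationError(f"dose-response table missing column {col!r}")
    return PoDataset(
        ca_er_um=df["ca_er_uM"].to_numpy(dtype=float),
        mean_po=df["mean_po"].to_numpy(dtype=float),
        sem=df["sem"].to_numpy(dtype=float) if "sem" in df.columns else None,
        n=df["n"].to_numpy() if "n" in df.columns else None,
    )


def read_cell_traces(
    path: str | Path, stim_start: float, stim_end: float
) -> list[CellRatioTrace]:
    """Read cell ratio traces from wide (time + one column per cell) or
    long (``cell_id,time_s,ratio``) CSV."""
    df = _read_table(path)
    if {"cell_id", "time_s", "ratio"}.issubset(df.columns):
        traces = []
        for cid, grp in df.groupby("cell_id", sort=True):
            traces.append(
                CellRatioTrace(
                    time=grp["time_s"].to_numpy(dtype=float),
                    ratio=grp["ratio"].to_numpy(dtype=float),
                    stim_start=stim_start,
                    stim_end=stim_end,
                    cell_id=str(cid),
                )
            )
        return traces
    time_col = next((c for c in df.columns if c.lower() in ("time", "time_s")), None)
    if time_col is None:
        raise ValidationError(
            "cell table must be long (cell_id,time_s,ratio) or wide with a time column"
        )
    t = df[time_col].to_numpy(dtype=float)
    return [
        CellRatioTrace(
            time=t,
            ratio=df[c].to_numpy(dtype=float),
            stim_start=stim_start,
            stim_end=stim_end,
            cell_id=str(c),
        )
        for c in df.columns
        if c != time_col
    ]


# ---------------------------------------------------------------------------
# results


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_summary(seed: int, config: dict, **extra) -> dict:
    return {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        **extra,
    }


def write_enrichment(
    result: EnrichmentResult, out_dir: str | Path, summary: dict | None = None
) -> Path:
    """Write ``enrichment.tsv`` (fixed column order) and an optional
    ``run_summary.json``; returns the table path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = ["protein_id", "post_mean_beta", "post_prob_slab", "lfsr", "selected"]
    path = out / "enrichment.tsv"
    result.table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
    if summary is not None:
        summary = dict(summary)
        summary["lfsr_threshold"] = result.threshold
        summary["global_false_sign_rate"] = result.global_false_sign_rate
        with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
    return path


def write_hill_fit(fit: HillFit, path: str | Path) -> None:
    payload = {
        "p_max": fit.p_max,
        "k_inh_um": fit.k_inh_um,
        "h_inh": fit.h_inh,
        "se_p_max": fit.se_p_max,
        "se_k_inh": fit.se_k_inh,
        "se_h_inh": fit.se_h_inh,
        "rss": fit.rss,
        "n_points": fit.n_points,
        "descent_sampled": fit.descent_sampled,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
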