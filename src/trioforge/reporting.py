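"""Cohort- and assay-level summary arithmetic.

Machine outputs always carry full precision; the "display" columns apply
the mixed rounding conventions used in cohort reports of this kind
(integer means where the fraction falls below display precision,
whole-percent call frequencies) and never feed back into computation.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

CLASS_ORDER = ("total", "snp", "indel", "missense", "frameshift", "stop_gain", "stop_lost")


def cohort_summary(
    class_counts: Mapping[str, tuple[int, int]] | pd.DataFrame,
    n_probands: int,
    n_controls: int,
) -> pd.DataFrame:
    """Totals, per-group means and pooled percentages per variant class.

    ``class_counts`` maps variant class -> (proband group total, control
    group total), or an equivalent DataFrame with columns ``variant_class``,
    ``proband_total``, ``control_total``. Percentages use the pooled grand
    total (proband + control totals of the ``total`` class; if absent, the
    sum over the supplied classes).
    """
    if n_probands <= 0 or n_controls <= 0:
        raise ValueError("group sizes must be positive")
    if isinstance(class_counts, pd.DataFrame):
        counts = {
            str(r["variant_class"]): (int(r["proband_total"]), int(r["control_total"]))
            for _, r in class_counts.iterrows()
        }
    else:
        counts = {k: (int(v[0]), int(v[1])) for k, v in class_counts.items()}
    if "total" in counts:
        grand = sum(counts["total"])
    else:
        grand = sum(p + c for p, c in counts.values())

    rows = []
    order = [c for c in CLASS_ORDER if c in counts] + [c for c in counts if c not in CLASS_ORDER]
    for cls in order:
        p_tot, c_tot = counts[cls]
        combined = p_tot + c_tot
        rows.append({
            "variant_class": cls,
            "proband_total": p_tot,
            "proband_mean": p_tot / n_probands,
            "control_total": c_tot,
            "control_mean": c_tot / n_controls,
            "combined_total": combined,
            "pct_probands": 100.0 * p_tot / grand if grand else 0.0,
            "pct_controls": 100.0 * c_tot / grand if grand else 0.0,
        })
    df = pd.DataFrame(rows)
    # display columns: integer mean when the fraction is below 2-decimal
    # display precision, else 2 decimals
    def disp(x: float) -> str:
        frac = abs(x - round(x))
        if round(x % 1, 2) in (0.0, 1.0) or frac < 0.005:
            return f"{round(x):d}"
        return f"{x:.2f}"

    df["proband_mean_display"] = df["proband_mean"].map(disp)
    df["control_mean_display"] = df["control_mean"].map(disp)
    return df


def assay_summary(plex: pd.DataFrame) -> pd.DataFrame:
    """Genotyping-assay call summaries: call frequency per SNP.

    Expects columns ``rsid, total, nocall`` (others such as ``position,
    gene, n_alleles, common, het, rage`` are passed through).
    ``call_frequency`` = 100 x (total - nocall) / total, kept at full
    precision; ``call_frequency_display`` rounds to a whole percent.
    """
    df = plex.copy()
    for col in ("total", "nocall"):
        if col not in df.columns:
            raise ValueError(f"assay table lacks required column {col!r}")
    if (df["total"] <= 0).any():
        raise ValueError("every assay needs total > 0")
    if (df["nocall"] > df["total"]).any() or (df["nocall"] < 0).any():
        raise ValueError("nocall must lie in [0, total]")
    df["call_frequency"] = 100.0 * (df["total"] - df["nocall"]) / df["total"]
    df["call_frequency_display"] = df["call_frequency"].round(0).astype(int)
    return df


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_manifest(
    stage_configs: Mapping[str, object],
    seed: Optional[int] = None,
    inputs: Optional[Mapping[str, str | Path]] = None,
    stage_outcomes: Optional[Mapping[str, Mapping]] = None,
    timestamp: Optional[str] = None,
) -> dict:
    """Reproducibility record: configs, seed, input checksums, outcomes.

    Deterministic except for the optional ``timestamp`` field, so two runs
    with identical configuration produce identical manifests apart from it.
    """
    manifest = {
        "seed": seed,
        "configs": {name: _jsonable(cfg) for name, cfg in (stage_configs or {}).items()},
        "inputs": {
            name: {"path": str(p), "sha256": file_checksum(p)}
            for name, p in (inputs or {}).items()
        },
        "stages": {name: _jsonable(out) for name, out in (stage_outcomes or {}).items()},
        "python": platform.python_version(),
    }
    if timestamp is not None:
        manifest["timestamp"] = timestamp
    return manifest


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
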