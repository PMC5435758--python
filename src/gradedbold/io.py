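"""Plain-text serialization of every object the pipeline exchanges.

Formats: CSV for time series (``time_s, label, echo1, echo2``), end-tidal
traces (``time_s, petco2_mmhg``) and level/group tables; JSON for
paradigms, fit results, ground truth and run manifests.  All tables use
the reporting units (percent, %/mmHg); the fraction/percent conversion
happens here and nowhere deeper.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fit import CalibrationResult, GroupSummary, HypercapniaLevel
from .preprocess import DualEchoSeries, EndTidalTrace, Paradigm

__all__ = [
    "write_dualecho_csv",
    "read_dualecho_csv",
    "write_endtidal_csv",
    "read_endtidal_csv",
    "write_paradigm_json",
    "read_paradigm_json",
    "levels_to_frame",
    "frame_to_levels",
    "write_levels_csv",
    "read_levels_csv",
    "write_result_json",
    "group_summaries_to_frame",
    "write_manifest",
]

DUALECHO_COLUMNS = ["time_s", "label", "echo1", "echo2"]
ENDTIDAL_COLUMNS = ["time_s", "petco2_mmhg"]
LEVEL_COLUMNS = ["subject", "delta_petco2_mmhg", "bold_percent", "cbf_percent"]


def write_dualecho_csv(series: DualEchoSeries, path) -> None:
    """Write the interleaved series; echo/TR metadata goes to a sidecar.

    A ``<name>.meta.json`` file with te1/te2/tr (seconds) is written next
    to the CSV so the series can be read back without extra arguments.
    """
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": series.time,
            "label": series.label,
            "echo1": series.echo1,
            "echo2": series.echo2,
        }
    ).to_csv(path, index=False)
    meta = {"te1_s": series.te1, "te2_s": series.te2, "tr_s": series.tr}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_dualecho_csv(
    path,
    te1: Optional[float] = None,
    te2: Optional[float] = None,
    tr: Optional[float] = None,
) -> DualEchoSeries:
    """Read a dual-echo CSV; timing metadata from args or the sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in DUALECHO_COLUMNS:
        if col not in df.columns:
            raise KeyError(f"missing column {col!r} in {path}")
    if te1 is None or te2 is None or tr is None:
        meta_path = path.with_suffix(".meta.json")
        if not meta_path.exists():
            raise FileNotFoundError(
                f"no te1/te2/tr given and no sidecar {meta_path} found"
            )
        meta = json.loads(meta_path.read_text())
        te1 = meta["te1_s"] if te1 is None else te1
        te2 = meta["te2_s"] if te2 is None else te2
        tr = meta["tr_s"] if tr is None else tr
    return DualEchoSeries(
        time=df["time_s"].to_numpy(),
        label=df["label"].to_numpy(),
        echo1=df["echo1"].to_numpy(),
        echo2=df["echo2"].to_numpy(),
        te1=float(te1),
        te2=float(te2),
        tr=float(tr),
    )


def write_endtidal_csv(trace: EndTidalTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "petco2_mmhg": trace.petco2}).to_csv(
        path, index=False
    )


def read_endtidal_csv(path) -> EndTidalTrace:
    df = pd.read_csv(path)
    for col in ENDTIDAL_COLUMNS:
        if col not in df.columns:
            raise KeyError(f"missing column {col!r} in {path}")
    return EndTidalTrace(
        times=df["time_s"].to_numpy(), petco2=df["petco2_mmhg"].to_numpy()
    )


def write_paradigm_json(paradigm: Paradigm, path) -> None:
    Path(path).write_text(json.dumps(paradigm.to_dict(), indent=1))


def read_paradigm_json(path) -> Paradigm:
    return Paradigm.from_dict(json.loads(Path(path).read_text()))


def levels_to_frame(
    levels: Sequence[HypercapniaLevel], subject: str = "sub-01"
) -> pd.DataFrame:
    """Percent-scale level table (one row per hypercapnia dose)."""
    return pd.DataFrame(
        {
            "subject": subject,
            "delta_petco2_mmhg": [lv.delta_petco2 for lv in levels],
            "bold_percent": [100.0 * lv.bold_frac for lv in levels],
            "cbf_percent": [100.0 * (lv.cbf_ratio - 1.0) for lv in levels],
        }
    )


def frame_to_levels(df: pd.DataFrame) -> dict[str, list[HypercapniaLevel]]:
    """Per-subject levels from a (possibly multi-subject) percent table."""
    for col in LEVEL_COLUMNS:
        if col not in df.columns:
            raise KeyError(f"missing column {col!r} in level table")
    out: dict[str, list[HypercapniaLevel]] = {}
    for subject, grp in df.groupby("subject", sort=False):
        out[str(subject)] = [
            HypercapniaLevel(
                delta_petco2=float(r["delta_petco2_mmhg"]),
                bold_frac=float(r["bold_percent"]) / 100.0,
                cbf_ratio=1.0 + float(r["cbf_percent"]) / 100.0,
            )
            for _, r in grp.iterrows()
        ]
    return out


def write_levels_csv(levels, path, subject: str = "sub-01") -> None:
    levels_to_frame(levels, subject).to_csv(path, index=False)


def read_levels_csv(path) -> dict[str, list[HypercapniaLevel]]:
    return frame_to_levels(pd.read_csv(path))


def write_result_json(
    two_param: CalibrationResult, one_param: CalibrationResult, path,
    subject: str = "sub-01",
) -> None:
    """Per-subject record with the graded and iso-metabolic fits side by side."""
    payload = {
        "subject": subject,
        "two_parameter": two_param.to_dict(),
        "one_parameter": one_param.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def group_summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Group table in reporting units, one row per summary/test mode."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "mode": s.mode,
                "n": f"{s.included_n}/{s.total_n}",
                "mean_m_percent": 100.0 * s.mean_m,
                "sem_m_percent": 100.0 * s.sem_m,
                "mean_kappa_percent_per_mmhg": _pct(s.mean_kappa),
                "sem_kappa_percent_per_mmhg": _pct(s.sem_kappa),
                "wilcoxon_p_kappa": s.wilcoxon_p_kappa,
                "mean_m_one_percent": _pct(s.mean_m_one),
                "sem_m_one_percent": _pct(s.sem_m_one),
                "mean_delta_m_percent": _pct(s.mean_delta_m),
                "sem_delta_m_percent": _pct(s.sem_delta_m),
                "wilcoxon_p_m_paired": s.wilcoxon_p_m_paired,
            }
        )
    return pd.DataFrame(rows)


def _pct(x: Optional[float]) -> Optional[float]:
    return None if x is None else 100.0 * x


def write_manifest(path, config: dict, seed: Optional[int] = None) -> None:
    """Reproducibility record: config echo, seed and library versions."""
    import scipy

    from . import __version__

    manifest = {
        "gradedbold": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
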