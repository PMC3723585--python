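"""TSV/TIFF/YAML interchange.

All tables are tab-separated with optional ``# key=value`` header comments;
times are minutes, intensities AU.  Images are 16-bit grayscale TIFF.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .simkit import CellTrace, SimConfig

__all__ = ["write_tsv", "read_tsv", "write_traces", "read_traces",
           "write_events", "read_events", "write_rates", "read_phase_counts",
           "write_phase_counts", "load_sim_config", "write_image",
           "read_image"]


def write_tsv(df: pd.DataFrame, path, header: Optional[dict] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _flatten(traces: Sequence[CellTrace]):
    for tr in traces:
        yield tr
        yield from _flatten(tr.progeny)


def write_traces(traces: Sequence[CellTrace], path, events_path=None,
                 truth_path=None, header: Optional[dict] = None) -> None:
    """Write lineage traces (and events / ground truth companions)."""
    rows, ev_rows, tr_rows = [], [], []
    for tr in _flatten(list(traces)):
        for i, t in enumerate(tr.times):
            row = {"cell_id": tr.cell_id,
                   "mother_id": tr.mother_id or "",
                   "time_min": t, "volume": tr.volume[i]}
            for ch, conc in tr.concentration.items():
                row[f"conc_{ch}"] = conc[i]
            rows.append(row)
        ev_rows += [{"cell_id": tr.cell_id, "event": "bud", "time_min": b}
                    for b in tr.bud_times]
        ev_rows += [{"cell_id": tr.cell_id, "event": "division", "time_min": d}
                    for d in tr.division_times]
        if tr.truth is not None:
            for i, t in enumerate(tr.times):
                tr_rows.append({"cell_id": tr.cell_id, "time_min": t,
                                "M_true": tr.truth["M"][i],
                                "A_true": tr.truth["A"][i],
                                "Pm_true": tr.truth["Pm"][i]})
    write_tsv(pd.DataFrame(rows), path, header)
    if events_path is not None:
        write_tsv(pd.DataFrame(ev_rows), events_path, header)
    if truth_path is not None and tr_rows:
        write_tsv(pd.DataFrame(tr_rows), truth_path, header)


def read_traces(path, events_path=None) -> list:
    """Rebuild CellTrace objects from trace (and optional events) TSVs."""
    df = read_tsv(path)
    events = read_tsv(events_path) if events_path else None
    out = []
    conc_cols = [c for c in df.columns if c.startswith("conc_")]
    for cid, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("time_min")
        buds, divs = [], []
        if events is not None:
            ev = events[events["cell_id"] == cid]
            buds = ev.loc[ev["event"] == "bud", "time_min"].tolist()
            divs = ev.loc[ev["event"] == "division", "time_min"].tolist()
        mother = g["mother_id"].iloc[0]
        out.append(CellTrace(
            cell_id=str(cid),
            mother_id=None if (pd.isna(mother) or mother == "") else str(mother),
            times=g["time_min"].to_numpy(dtype=float),
            volume=g["volume"].to_numpy(dtype=float),
            concentration={c[len("conc_"):]: g[c].to_numpy(dtype=float)
                           for c in conc_cols},
            bud_times=buds, division_times=divs))
    return out


def write_events(traces: Sequence[CellTrace], path,
                 header: Optional[dict] = None) -> None:
    rows = []
    for tr in _flatten(list(traces)):
        rows += [{"cell_id": tr.cell_id, "event": "bud", "time_min": b}
                 for b in tr.bud_times]
        rows += [{"cell_id": tr.cell_id, "event": "division", "time_min": d}
                 for d in tr.division_times]
    write_tsv(pd.DataFrame(rows), path, header)


def read_events(path) -> pd.DataFrame:
    return read_tsv(path)


def write_rates(rates_list, path, header: Optional[dict] = None) -> None:
    rows = []
    for r in rates_list:
        for i, t in enumerate(r.times):
            rows.append({"cell_id": r.cell_id, "time_min": t,
                         "M": r.M[i], "A": r.A[i],
                         "low_confidence": int(r.low_confidence[i])})
    write_tsv(pd.DataFrame(rows), path, header)


def write_phase_counts(df: pd.DataFrame, path,
                       header: Optional[dict] = None) -> None:
    write_tsv(df[["cell_id", "phase", "count"]], path, header)


def read_phase_counts(path) -> pd.DataFrame:
    df = read_tsv(path)
    needed = {"cell_id", "phase", "count"}
    if not needed <= set(df.columns):
        raise ValueError(f"phase-count table needs columns {sorted(needed)}")
    return df


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg


def write_image(image: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.clip(image, 0, 65535).astype(np.uint16))


def read_image(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path).astype(float)
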