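"""Plain-text I/O: gradient count tables (TSV), truth sets (JSON), spectra (CSV).

One TSV holds all gradients of an experiment, fractions as rows: the
metadata columns ``gradient_id, fraction_id, density_g_ml, label_status,
medium, timepoint, copy_quant`` followed by one column per OTU.  Spectra
travel as long-format CSV with columns ``cell_id, strain, at_percent,
wavenumber, intensity``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .raman import Spectrum
from .sip import GradientFractionTable

__all__ = [
    "write_gradient_tables",
    "read_gradient_tables",
    "write_truth",
    "read_truth",
    "write_spectra_csv",
    "read_spectra_csv",
]

_META_COLS = ["gradient_id", "fraction_id", "density_g_ml", "label_status", "medium",
              "timepoint", "copy_quant"]


def write_gradient_tables(tables: Sequence[GradientFractionTable], path: str | Path) -> None:
    """Write all gradients of an experiment to one fractions-as-rows TSV."""
    rows = []
    for t in tables:
        for frac_id in t.counts.index:
            row = {
                "gradient_id": t.gradient_id,
                "fraction_id": frac_id,
                "density_g_ml": t.densities[frac_id],
                "label_status": t.label_status,
                "medium": t.medium,
                "timepoint": t.timepoint,
                "copy_quant": t.copy_quant[frac_id] if t.copy_quant is not None else np.nan,
            }
            row.update(t.counts.loc[frac_id].to_dict())
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gradient_tables(path: str | Path) -> list[GradientFractionTable]:
    """Read gradients back from the TSV layout written by :func:`write_gradient_tables`."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    otu_cols = [c for c in frame.columns if c not in _META_COLS]
    if not otu_cols:
        raise ValueError(f"{path}: no OTU count columns")
    tables = []
    for gid, sub in frame.groupby("gradient_id", sort=False):
        sub = sub.set_index("fraction_id")
        copy_quant = sub["copy_quant"]
        tables.append(
            GradientFractionTable(
                gradient_id=str(gid),
                label_status=str(sub["label_status"].iloc[0]),
                medium=str(sub["medium"].iloc[0]),
                timepoint=float(sub["timepoint"].iloc[0]),
                densities=sub["density_g_ml"].astype(float),
                counts=sub[otu_cols].astype(int),
                copy_quant=None if copy_quant.isna().all() else copy_quant.astype(float),
            )
        )
    return tables


def write_truth(labelled_otu_ids, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"labelled_otu_ids": sorted(labelled_otu_ids)}, indent=2))


def read_truth(path: str | Path) -> frozenset:
    return frozenset(json.loads(Path(path).read_text())["labelled_otu_ids"])


def write_spectra_csv(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as long-format CSV (cell_id, strain, at_percent, wavenumber, intensity)."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": s.cell_id,
                "strain": s.strain,
                "at_percent": s.at_percent,
                "wavenumber": s.wavenumbers,
                "intensity": s.intensities,
            }
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    frame = pd.read_csv(path)
    required = {"cell_id", "wavenumber", "intensity"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    spectra = []
    for cell_id, sub in frame.groupby("cell_id", sort=False):
        sub = sub.sort_values("wavenumber")
        spectra.append(
            Spectrum(
                wavenumbers=sub["wavenumber"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
                strain=str(sub["strain"].iloc[0]) if "strain" in sub else "",
                at_percent=float(sub["at_percent"].iloc[0]) if "at_percent" in sub else None,
                cell_id=str(cell_id),
            )
        )
    return spectra
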