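"""Readers and writers for the pipeline's flat-file formats.

Tables are CSV or TSV (sniffed from the extension), sequences are aligned
FASTA, trees are Newick with bootstrap supports as internal-node labels.
The packaged reference tables (printed growth rates and biodiesel indices
for the strain collection) are exposed via ``load_printed_*``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .bioassay import DoseResponsePanel, InhibitionResult
from .fame import FameProfile, RawPeakTable, normalize_profile
from .growth import GrowthCurve, GrowthFit
from .phylo import Alignment, PhylotypeAssignment

__all__ = [
    "read_growth_table",
    "write_growth_table",
    "write_growth_fits",
    "read_fame_table",
    "write_fame_table",
    "read_bioassay_table",
    "write_bioassay_table",
    "write_inhibition_results",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_newick",
    "write_newick",
    "write_phylotypes",
    "write_json",
    "load_printed_growth_table",
    "load_printed_index_table",
]

GROWTH_COLUMNS = ["strain", "time_h", "value", "measure"]
BIOASSAY_COLUMNS = ["strain", "concentration_mg_L", "replicate", "time_h", "fluorescence"]


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; found {list(df.columns)}"
        )
    return df


# ---------------------------------------------------------------------------
# growth


def read_growth_table(path: str | Path) -> list[GrowthCurve]:
    """Long-format growth series: strain, time_h, value, measure."""
    df = _read_table(path, GROWTH_COLUMNS)
    curves = []
    for strain, grp in df.groupby("strain", sort=True):
        measures = set(grp["measure"])
        # OD is preferred when both OD and counts were recorded
        measure = "od550" if "od550" in measures else sorted(measures)[0]
        sub = grp[grp["measure"] == measure].sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain_id=str(strain),
                times=tuple(sub["time_h"].astype(float)),
                densities=tuple(sub["value"].astype(float)),
                measure=measure,
            )
        )
    return curves


def write_growth_table(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    rows = [
        {"strain": c.strain_id, "time_h": t, "value": d, "measure": c.measure}
        for c in curves
        for t, d in zip(c.times, c.densities)
    ]
    pd.DataFrame(rows, columns=GROWTH_COLUMNS).to_csv(path, sep=_sep(path), index=False)


def write_growth_fits(fits: Iterable[GrowthFit], path: str | Path) -> None:
    rows = [
        {
            "strain": f.strain_id,
            "mu_per_day": f.mu,
            "generation_time_h": f.generation_time_h,
            "window_start": f.window[0],
            "window_stop": f.window[1],
            "r_squared": f.r_squared,
            "n_points": f.n_points,
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


# ---------------------------------------------------------------------------
# FAME tables


def read_fame_table(path: str | Path, normalize: bool = True) -> list[FameProfile]:
    """FAME table in long (strain, species, value) or wide (strain x species) form.

    The layout is auto-detected from the header. Values may be raw peak
    areas; profiles are normalised to 100 wt% (dropping the C19:0 internal
    standard if present) unless ``normalize`` is False, in which case the
    values must already sum to 100.
    """
    df = pd.read_csv(path, sep=_sep(path))
    if "strain" not in df.columns:
        raise ValueError(f"{path}: no 'strain' column; found {list(df.columns)}")
    if {"species", "value"} <= set(df.columns):  # long format
        tables = {
            str(strain): dict(zip(grp["species"], grp["value"].astype(float)))
            for strain, grp in df.groupby("strain", sort=True)
        }
    else:  # wide format: every non-strain column is a species
        species = [c for c in df.columns if c != "strain"]
        if not species:
            raise ValueError(f"{path}: no species columns")
        tables = {
            str(row["strain"]): {sp: float(row[sp]) for sp in species}
            for _, row in df.iterrows()
        }
    profiles = []
    for sid, peaks in tables.items():
        peaks = {k: v for k, v in peaks.items() if pd.notna(v)}
        if normalize:
            profiles.append(normalize_profile(RawPeakTable(strain_id=sid, peaks=peaks)))
        else:
            profiles.append(FameProfile(strain_id=sid, abundances=peaks))
    return profiles


def write_fame_table(profiles: Iterable[FameProfile], path: str | Path) -> None:
    rows = [
        {"strain": p.strain_id, "species": sp, "value": v}
        for p in profiles
        for sp, v in sorted(p.abundances.items())
    ]
    pd.DataFrame(rows, columns=["strain", "species", "value"]).to_csv(
        path, sep=_sep(path), index=False
    )


# ---------------------------------------------------------------------------
# bioassay


def read_bioassay_table(path: str | Path) -> list[DoseResponsePanel]:
    df = _read_table(path, BIOASSAY_COLUMNS)
    return [
        DoseResponsePanel(
            strain_id=str(strain), data=grp.drop(columns="strain").reset_index(drop=True)
        )
        for strain, grp in df.groupby("strain", sort=True)
    ]


def write_bioassay_table(panels: Iterable[DoseResponsePanel], path: str | Path) -> None:
    frames = []
    for p in panels:
        df = p.data.copy()
        df.insert(0, "strain", p.strain_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_sep(path), index=False)


def write_inhibition_results(
    results: Iterable[InhibitionResult], path: str | Path
) -> None:
    frames = []
    for r in results:
        df = r.per_concentration.copy()
        df.insert(0, "strain", r.strain_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_sep(path), index=False)


# ---------------------------------------------------------------------------
# sequences and trees


def read_alignment_fasta(path: str | Path) -> Alignment:
    """Aligned FASTA; ragged (unaligned) input is rejected explicitly."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(
            f"{path}: sequences are not aligned (lengths {sorted(lengths)})"
        )
    return Alignment(
        ids=tuple(r.id for r in records),
        seqs=tuple(str(r.seq).upper() for r in records),
    )


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_phylotypes(assignment: PhylotypeAssignment, path: str | Path) -> None:
    rows = [
        {"taxon": t, "phylotype": pid}
        for t, pid in sorted(assignment.assignment.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


# ---------------------------------------------------------------------------
# packaged reference tables (printed study values, used as inputs)


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("algascreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_printed_growth_table() -> pd.DataFrame:
    """Printed growth rates (d^-1) and generation times (h) for the 43 strains."""
    return _load_packaged("growth_rates.csv")


def load_printed_index_table() -> pd.DataFrame:
    """Printed biodiesel indices (CN, IV, DU, LCSF, SV, CFPP) for the 34 axenic strains."""
    return _load_packaged("biodiesel_indices.csv")
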