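"""Readers and writers for clone FASTA files, sample sheets, density tables
and the tabular outputs of the divergence caller.

Conventions
-----------
* Clone sequences are stored 5'->3' on the G-rich strand with the
  centromere-proximal end at position 0.  Input FASTA files are expected in
  that orientation; pass ``revcomp=True`` for C-rich strand submissions.
* All positions and lengths reported in tables are 1-based nucleotides;
  internal coordinates are 0-based half-open.
* Tables are plain TSV with a header row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_VALID_BASES = frozenset("ACGT")

SAMPLE_SHEET_COLUMNS = ["clone_id", "telomere_id", "strain_id", "genotype", "generations"]
DENSITY_COLUMNS = ["strain_id", "genotype", "replicate_id", "day", "density"]
CALLS_COLUMNS = [
    "clone_id",
    "telomere_id",
    "strain_id",
    "genotype",
    "generations",
    "clone_length_nt",
    "undiverged_length_nt",
    "diverged",
    "divergence_point_1based",
    "truncation",
    "reason",
]


@dataclass
class CloneSequence:
    """One sequenced telomere clone with its sample metadata.

    ``bases`` is the cloned telomere on the G-rich strand, proximal end
    first; ``generations`` is the number of population doublings since
    clonal isolation (e.g. ~30 for the pre-senescent sets).
    """

    clone_id: str
    telomere_id: str
    strain_id: str
    genotype: str
    generations: float
    bases: str

    def __post_init__(self) -> None:
        self.bases = str(self.bases).upper()
        if not self.bases:
            raise ValueError(f"clone {self.clone_id!r}: empty sequence")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"clone {self.clone_id!r}: non-ACGT characters after normalization: "
                f"{sorted(bad)}"
            )
        if self.generations < 0:
            raise ValueError(f"clone {self.clone_id!r}: generations must be >= 0")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class TelomereSet:
    """All clones of one telomere locus from one clonal population.

    This is the unit of divergence analysis: clones in a set share a
    centromere-proximal region of stable sequence and may differ distally.
    """

    telomere_id: str
    strain_id: str
    genotype: str
    generations: float
    clones: list[CloneSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.clones:
            if (c.telomere_id, c.strain_id, c.generations) != (
                self.telomere_id,
                self.strain_id,
                self.generations,
            ):
                raise ValueError(
                    f"clone {c.clone_id!r} does not belong to set "
                    f"({self.telomere_id}, {self.strain_id}, {self.generations})"
                )

    def __len__(self) -> int:
        return len(self.clones)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV sample sheet mapping clone ids to samples."""
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {missing}")
    dup = df["clone_id"][df["clone_id"].duplicated()]
    if len(dup):
        raise ValueError(f"sample sheet {path}: duplicate clone ids {sorted(set(dup))}")
    df["generations"] = pd.to_numeric(df["generations"])
    if (df["generations"] < 0).any():
        raise ValueError(f"sample sheet {path}: negative generations")
    return df[SAMPLE_SHEET_COLUMNS].copy()


def write_sample_sheet(rows: pd.DataFrame, path: str | Path) -> None:
    rows[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clone_fasta(
    fasta_path: str | Path,
    sample_sheet: str | Path | pd.DataFrame,
    revcomp: bool = False,
) -> list[TelomereSet]:
    """Read clone FASTA and group records into :class:`TelomereSet`\\ s.

    Records are grouped by (telomere_id, strain_id, generations), preserving
    the clone order of the file.  Sets with a single clone cannot be
    analysed for divergence and are dropped with a warning.
    """
    if isinstance(sample_sheet, (str, Path)):
        sheet = read_sample_sheet(sample_sheet)
    else:
        sheet = sample_sheet
    meta = sheet.set_index("clone_id")

    groups: dict[tuple, TelomereSet] = {}
    n_records = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_records += 1
        if rec.id not in meta.index:
            raise ValueError(
                f"FASTA record {rec.id!r} not present in the sample sheet"
            )
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        if revcomp:
            seq = str(Seq(seq).reverse_complement())
        row = meta.loc[rec.id]
        clone = CloneSequence(
            clone_id=rec.id,
            telomere_id=str(row["telomere_id"]),
            strain_id=str(row["strain_id"]),
            genotype=str(row["genotype"]),
            generations=float(row["generations"]),
            bases=seq,
        )
        key = (clone.telomere_id, clone.strain_id, clone.generations)
        if key not in groups:
            groups[key] = TelomereSet(
                telomere_id=clone.telomere_id,
                strain_id=clone.strain_id,
                genotype=clone.genotype,
                generations=clone.generations,
            )
        groups[key].clones.append(clone)
    if n_records == 0:
        raise ValueError(f"FASTA {fasta_path}: no records")

    out = []
    for key, ts in groups.items():
        if len(ts) < 2:
            warnings.warn(
                f"telomere set {key} has a single clone; excluded from analysis",
                stacklevel=2,
            )
            continue
        out.append(ts)
    return out


def write_clone_fasta(clones: Iterable[CloneSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in clones:
            fh.write(f">{c.clone_id}\n")
            for i in range(0, len(c.bases), width):
                fh.write(c.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# divergence-call tables


def calls_to_frame(calls: Sequence) -> pd.DataFrame:
    """Convert DivergenceCall objects (with metadata attached) to a table."""
    rows = []
    for c in calls:
        rows.append(
            {
                "clone_id": c.clone_id,
                "telomere_id": c.telomere_id,
                "strain_id": c.strain_id,
                "genotype": c.genotype,
                "generations": c.generations,
                "clone_length_nt": c.clone_length_nt,
                "undiverged_length_nt": c.undiverged_length_nt,
                "diverged": c.diverged,
                "divergence_point_1based": c.divergence_point_1based,
                "truncation": c.truncation,
                "reason": c.reason,
            }
        )
    return pd.DataFrame(rows, columns=CALLS_COLUMNS)


def write_calls_table(calls: Sequence, path: str | Path) -> None:
    """Write divergence calls as a TSV; round-trips through read_calls_table."""
    if len(calls) == 0:
        raise ValueError("no calls to write")
    df = calls_to_frame(calls)
    df["divergence_point_1based"] = df["divergence_point_1based"].astype("Int64")
    df.to_csv(path, sep="\t", index=False)


def read_calls_table(path: str | Path) -> list:
    from .caller import DivergenceCall  # local import: io does not depend on caller at import time

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALLS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calls table {path}: missing columns {missing}")
    out = []
    for _, r in df.iterrows():
        dp = r["divergence_point_1based"]
        out.append(
            DivergenceCall(
                clone_id=str(r["clone_id"]),
                undiverged_length_nt=int(r["undiverged_length_nt"]),
                diverged=bool(r["diverged"]),
                divergence_point_1based=None if pd.isna(dp) else int(dp),
                truncation=bool(r["truncation"]),
                reason=str(r["reason"]),
                telomere_id=str(r["telomere_id"]),
                strain_id=str(r["strain_id"]),
                genotype=str(r["genotype"]),
                generations=float(r["generations"]),
                clone_length_nt=int(r["clone_length_nt"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# density tables (liquid-culture senescence assays)


def validate_density_table(df: pd.DataFrame, origin: str = "density table") -> pd.DataFrame:
    missing = [c for c in DENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{origin}: missing columns {missing}")
    df = df[DENSITY_COLUMNS].copy()
    df["day"] = df["day"].astype(int)
    df["density"] = pd.to_numeric(df["density"])
    if (df["density"] <= 0).any():
        raise ValueError(f"{origin}: non-positive density")
    if (df["day"] < 1).any():
        raise ValueError(f"{origin}: day must be a positive integer")
    key = ["strain_id", "replicate_id", "day"]
    if df.duplicated(key).any():
        dups = df[df.duplicated(key, keep=False)][key].drop_duplicates()
        raise ValueError(f"{origin}: duplicate measurements:\n{dups}")
    for (strain, rep), grp in df.groupby(["strain_id", "replicate_id"]):
        days = sorted(grp["day"])
        if days != list(range(1, len(days) + 1)):
            raise ValueError(
                f"{origin}: replicate ({strain}, {rep}) days are not consecutive "
                f"from 1: {days}"
            )
    return df


def read_density_table(path: str | Path) -> pd.DataFrame:
    """Read a daily cell-density TSV (cells/ml, one row per strain/replicate/day)."""
    df = pd.read_csv(path, sep="\t")
    return validate_density_table(df, origin=f"density table {path}")


def write_density_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_density_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# rate tables


def write_rates_table(estimates: Sequence, path: str | Path) -> None:
    """Write RateEstimate objects (one per labelled group) to TSV."""
    rows = []
    for label, est in estimates:
        rows.append(
            {
                "label": label,
                "n_clones": est.n_clones,
                "n_diverged": est.n_diverged,
                "fraction": est.fraction,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "generations": est.generations,
                "per_generation_rate": est.per_generation_rate,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
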