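"""sgRNA library handling and read quantification.

Turns a library table plus per-sample reads (or a precomputed count table)
into a validated raw count matrix ready for enrichment analysis. Reads are
assumed to start directly with the 20-nt spacer (the screen's sequencing
recipe uses dark cycles to skip the vector sequence); a fixed offset is
configurable for other library preps.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

NTC_TOKEN = "NTC"
SPACER_LEN = 20
CONDITIONS = ("input", "empty", "yap")
_BASES = "ACGT"


class LibraryError(ValueError):
    """Malformed or inconsistent sgRNA library."""


class CountError(ValueError):
    """Malformed count matrix or sample sheet."""


@dataclass(frozen=True)
class SgrnaRecord:
    """One guide: unique id, target gene (or the nontargeting token), 20-nt spacer."""

    sgrna_id: str
    gene: str
    spacer: str

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN or set(self.spacer) - set(_BASES):
            raise LibraryError(
                f"sgRNA {self.sgrna_id!r}: spacer must be {SPACER_LEN} nt over ACGT, "
                f"got {self.spacer!r}"
            )


@dataclass
class LibraryDesign:
    """Ordered sgRNA library with a gene index and the nontargeting subset.

    ``table`` has columns ``sgrna_id``, ``gene``, ``spacer`` (one row per
    guide, order preserved). Nontargeting controls carry gene == "NTC".
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sgrna_id", "gene", "spacer"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise LibraryError(f"library table missing column(s) {missing}")
        self.table = self.table[required].reset_index(drop=True).astype(str)
        for row, rec in enumerate(self.table.itertuples(index=False), start=1):
            if len(rec.spacer) != SPACER_LEN or set(rec.spacer) - set(_BASES):
                raise LibraryError(
                    f"row {row} (sgRNA {rec.sgrna_id!r}): spacer must be "
                    f"{SPACER_LEN} nt over ACGT, got {rec.spacer!r}"
                )
        for col in ("sgrna_id", "spacer"):
            dup = self.table[col][self.table[col].duplicated()]
            if not dup.empty:
                raise LibraryError(f"duplicate {col} value(s): {sorted(set(dup))[:5]}")

    # -- derived views -------------------------------------------------
    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.table["sgrna_id"])

    @property
    def genes(self) -> pd.Index:
        """Targeted genes, excluding the nontargeting token."""
        g = self.table["gene"]
        return pd.Index(g[g != NTC_TOKEN].unique())

    @property
    def ntc_ids(self) -> pd.Index:
        t = self.table
        return pd.Index(t.loc[t["gene"] == NTC_TOKEN, "sgrna_id"])

    def gene_to_sgrnas(self) -> dict[str, list[str]]:
        return {
            g: list(sub["sgrna_id"])
            for g, sub in self.table.groupby("gene", sort=False)
        }

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountMatrix:
    """Raw integer sgRNA x sample counts with sample metadata.

    ``counts``: DataFrame indexed by sgrna_id, one column per sample_id.
    ``samples``: DataFrame indexed by sample_id with columns ``condition``
    (one of input/empty/yap) and ``replicate`` (int).
    ``unassigned``: per-sample reads not attributable to any guide (optional).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unassigned: pd.Series | None = None

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.samples.index):
            extra = set(self.counts.columns) - set(self.samples.index)
            raise CountError(f"samples missing from sample sheet: {sorted(extra)}")
        bad = self.samples.loc[
            ~self.samples["condition"].isin(CONDITIONS), "condition"
        ]
        if not bad.empty:
            raise CountError(
                f"unknown condition token(s) {sorted(set(bad))}; "
                f"expected one of {CONDITIONS}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise CountError("counts must be numeric")
        if np.any(vals < 0) or np.any(vals != np.floor(vals)):
            raise CountError("counts must be nonnegative integers")
        self.counts = self.counts.astype(np.int64)
        pairs = self.samples.loc[list(self.counts.columns), ["condition", "replicate"]]
        dup = pairs[pairs.duplicated()]
        if not dup.empty:
            raise CountError(
                f"duplicate (condition, replicate) pairs: {dup.to_records().tolist()}"
            )

    @property
    def replicates(self) -> list[int]:
        return sorted(self.samples.loc[list(self.counts.columns), "replicate"].unique())

    def sample_for(self, condition: str, replicate: int) -> str:
        sub = self.samples.loc[list(self.counts.columns)]
        hit = sub[(sub["condition"] == condition) & (sub["replicate"] == replicate)]
        if len(hit) != 1:
            raise CountError(f"no unique sample for ({condition}, rep {replicate})")
        return str(hit.index[0])

    def restrict_to(self, library: LibraryDesign) -> "CountMatrix":
        missing = set(self.counts.index) - set(library.sgrna_ids)
        if missing:
            raise CountError(
                f"count matrix contains sgRNAs absent from the library: "
                f"{sorted(missing)[:5]}"
            )
        counts = self.counts.reindex(library.sgrna_ids, fill_value=0)
        return CountMatrix(counts, self.samples, self.unassigned)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_library(path: str | Path) -> LibraryDesign:
    """Parse and validate a tab-delimited library table (sgrna_id, gene, spacer)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return LibraryDesign(_read_table(path))


def write_library(library: LibraryDesign, path: str | Path, header: str = "") -> None:
    _write_table(library.table, path, header)


def read_counts(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Load a count matrix and its sample sheet into a validated CountMatrix."""
    raw = pd.read_csv(path, sep="\t", comment="#")
    if "sgrna_id" not in raw.columns:
        raise CountError("count matrix must have an sgrna_id column")
    counts = raw.set_index("sgrna_id")
    sheet = _read_table(sample_sheet_path)
    for col in ("sample_id", "condition", "replicate"):
        if col not in sheet.columns:
            raise CountError(f"sample sheet missing column {col!r}")
    samples = sheet.set_index("sample_id")
    samples["replicate"] = samples["replicate"].astype(int)
    return CountMatrix(counts, samples)


def write_counts(cm: CountMatrix, counts_path: str | Path,
                 samples_path: str | Path, header: str = "") -> None:
    _write_table(cm.counts.reset_index(), counts_path, header)
    _write_table(cm.samples.reset_index(), samples_path, header)


def _write_table(frame: pd.DataFrame, path: str | Path, header: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

def _open_fastq(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _one_mismatch_lookup(library: LibraryDesign) -> dict[str, str | None]:
    """Map every 20-mer within Hamming distance 1 of a spacer to its sgRNA.

    A variant reachable from two different spacers maps to None (ambiguous);
    exact spacer sequences always win over a 1-mismatch neighbour.
    """
    exact = dict(zip(library.table["spacer"], library.table["sgrna_id"]))
    lut: dict[str, str | None] = {}
    for spacer, sid in exact.items():
        for i in range(SPACER_LEN):
            for b in _BASES:
                if b == spacer[i]:
                    continue
                variant = spacer[:i] + b + spacer[i + 1:]
                if variant in exact:
                    continue
                if variant in lut and lut[variant] != sid:
                    lut[variant] = None  # tie between two spacers: discard
                else:
                    lut.setdefault(variant, sid)
    lut.update(exact)
    return lut


def count_reads(
    library: LibraryDesign,
    fastq_path: str | Path,
    mismatch_mode: str = "exact",
    offset: int = 0,
) -> tuple[pd.Series, int]:
    """Count reads per sgRNA for one sample.

    Each read's 20-mer at ``offset`` is compared with the library spacers.
    ``exact`` increments the unique matching guide; ``one_mismatch``
    additionally accepts a unique guide at Hamming distance 1, discarding
    ties. Everything else (no match, short read) goes to unassigned.

    Returns (counts indexed like the library, unassigned read count);
    assigned + unassigned always equals the number of reads.
    """
    if mismatch_mode not in ("exact", "one_mismatch"):
        raise ValueError(f"unknown mismatch_mode {mismatch_mode!r}")
    if mismatch_mode == "exact":
        lut: dict[str, str | None] = dict(
            zip(library.table["spacer"], library.table["sgrna_id"])
        )
    else:
        lut = _one_mismatch_lookup(library)

    tallies: dict[str, int] = {}
    unassigned = 0
    n_reads = 0
    with _open_fastq(fastq_path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            n_reads += 1
            seq = str(rec.seq)
            key = seq[offset:offset + SPACER_LEN]
            if len(key) < SPACER_LEN:
                unassigned += 1
                continue
            sid = lut.get(key)
            if sid is None:
                unassigned += 1
            else:
                tallies[sid] = tallies.get(sid, 0) + 1
    if n_reads == 0:
        import warnings

        warnings.warn(f"empty FASTQ: {fastq_path}", stacklevel=2)
    counts = pd.Series(tallies, dtype=np.int64).reindex(
        library.sgrna_ids, fill_value=0
    )
    counts.index.name = "sgrna_id"
    return counts, unassigned


def counts_from_fastqs(
    library: LibraryDesign,
    fastqs: dict[str, str | Path],
    samples: pd.DataFrame,
    mismatch_mode: str = "exact",
    offset: int = 0,
) -> CountMatrix:
    """Quantify several per-sample FASTQ files into one CountMatrix."""
    cols = {}
    unassigned = {}
    for sample_id, path in fastqs.items():
        counts, una = count_reads(library, path, mismatch_mode, offset)
        cols[sample_id] = counts
        unassigned[sample_id] = una
    matrix = pd.DataFrame(cols)
    matrix.index.name = "sgrna_id"
    return CountMatrix(matrix, samples, pd.Series(unassigned, dtype=np.int64))
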