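"""Synthetic rescue-screen generator with known ground truth.

Emulates a pooled CRISPR knockout screen under forced-YAP cytostasis:
a library of ~4 guides per gene plus nontargeting controls is propagated
through three arms (Input harvested at day 10; Empty-vector and
YAP-expressing arms at day 25) in several biological replicates. Gene
knockouts act multiplicatively on clone abundance in the YAP arm only:
knocking out a cytostasis *effector* rescues growth (enrichment), knocking
out a YAP *inhibitor* deepens arrest (depletion). Sequencing counts are
overdispersed (Poisson-lognormal), and per-guide knockout efficacy is
heterogeneous, so only a random subset of a gene's guides carry its effect.

The generative model is
    abundance_input = base                       base ~ LogNormal(0, library_skew_sd)
    abundance_empty = base * drift               drift ~ LogNormal(0, drift_sd)
    abundance_yap   = base * drift' * fold^s     s = guide-active indicator
with fold = effect_fold for effector genes, 1/effect_fold for inhibitors,
1 otherwise; abundances are renormalized within each sample (sequencing
measures composition, not absolute cell number) and counts drawn as
Poisson(depth * rel_abundance * eps), eps ~ LogNormal(-sigma^2/2, sigma)
with sigma = baseline_dispersion, giving negative-binomial-like noise.

One RNG substream per named stage and per (condition, replicate) sample is
derived from the master seed, so e.g. adding replicates never perturbs
earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import (
    CONDITIONS,
    NTC_TOKEN,
    SPACER_LEN,
    CountMatrix,
    LibraryDesign,
    write_counts,
    write_library,
)

_BASES = np.array(list("ACGT"))

EFFECTOR = "effector"
INHIBITOR = "inhibitor"
NULL = "null"


@dataclass(frozen=True)
class SimConfig:
    """Screen-design and noise parameters for the synthetic generator.

    Library design defaults mirror the screen this package scores:
    950 targeted genes x 4 sgRNAs plus 50 nontargeting controls, in
    biological quadruplicate. Noise defaults describe a well-executed,
    well-powered screen; see docs/methods.md for the reasoning.
    """

    n_genes: int = 950
    sgrnas_per_gene: int = 4
    n_ntc: int = 50
    n_replicates: int = 4
    effector_fraction: float = 0.02
    inhibitor_fraction: float = 0.02
    effect_fold: float = 3.0          # multiplicative growth rescue per knockout
    sgrna_active_prob: float = 0.75   # chance a guide yields a functional knockout
    library_skew_sd: float = 0.5      # ln-scale spread of library representation
    baseline_dispersion: float = 0.15  # ln-scale count overdispersion (NB-like)
    mean_depth: float = 500.0         # expected reads per sgRNA per sample
    drift_sd: float = 0.10            # ln-scale passage drift, day 10 -> day 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.sgrnas_per_gene < 1 or self.n_replicates < 1:
            raise ValueError("n_genes, sgrnas_per_gene, n_replicates must be >= 1")
        if self.n_ntc < 0:
            raise ValueError("n_ntc must be >= 0")
        for name in ("effector_fraction", "inhibitor_fraction", "sgrna_active_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effector_fraction + self.inhibitor_fraction > 1.0:
            raise ValueError("effector_fraction + inhibitor_fraction must be <= 1")
        if self.effect_fold <= 1.0 and (
            self.effector_fraction > 0 or self.inhibitor_fraction > 0
        ):
            raise ValueError("effect_fold must be > 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for name in ("library_skew_sd", "baseline_dispersion", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_sgrnas(self) -> int:
        return self.n_genes * self.sgrnas_per_gene + self.n_ntc


@dataclass
class SimTruth:
    """Ground truth of a simulated screen.

    ``genes``: indexed by gene; columns ``klass`` (effector/inhibitor/null)
    and ``effect_fold``. ``sgrnas``: indexed by sgrna_id; columns ``gene``
    and ``active`` (bool). NTC guides are always null and inactive.
    """

    genes: pd.DataFrame
    sgrnas: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Flat per-sgRNA truth table: sgrna_id, gene, class, effect_fold, active."""
        out = self.sgrnas.reset_index()
        gene_info = self.genes.rename(columns={"klass": "class"})
        out = out.merge(
            gene_info.reset_index().rename(columns={"index": "gene"}),
            on="gene", how="left",
        )
        out["class"] = out["class"].fillna(NULL)
        out["effect_fold"] = out["effect_fold"].fillna(1.0)
        return out[["sgrna_id", "gene", "class", "effect_fold", "active"]]


def read_truth(path: str | Path) -> SimTruth:
    """Load a flat truth table written by write_fixture back into SimTruth."""
    # keep_default_na: the class label "null" must stay a string, not NaN
    flat = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                       na_values=[""])
    required = {"sgrna_id", "gene", "class", "effect_fold", "active"}
    missing = required - set(flat.columns)
    if missing:
        raise ValueError(f"truth table missing column(s) {sorted(missing)}")
    targeted = flat[flat["gene"] != NTC_TOKEN]
    genes = (
        targeted.groupby("gene", sort=False)[["class", "effect_fold"]]
        .first()
        .rename(columns={"class": "klass"})
    )
    genes.index.name = "gene"
    sgrnas = flat.set_index("sgrna_id")[["gene", "active"]].copy()
    sgrnas["active"] = sgrnas["active"].astype(bool)
    return SimTruth(genes, sgrnas)


class SpacerSpaceExhausted(RuntimeError):
    """Could not place enough mutually distinct spacers."""


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


_STREAM_SPACERS = 0
_STREAM_CLASSES = 1
_STREAM_ACTIVE = 2
_STREAM_SAMPLES = 3  # + (condition index, replicate)
_STREAM_BASE = 4     # + replicate
_STREAM_FASTQ = 5


def _random_spacers(
    n: int, rng: np.random.Generator, min_distance: int = 2,
    max_tries_factor: int = 200,
) -> list[str]:
    """Draw n distinct 20-mers, pairwise Hamming distance >= min_distance.

    For min_distance=2 every accepted spacer's full 1-mismatch neighbourhood
    is blacklisted, making later exact-match FASTQ counting unambiguous even
    under single sequencing errors.
    """
    taken: set[str] = set()
    forbidden: set[str] = set()
    out: list[str] = []
    tries = 0
    limit = max_tries_factor * n
    while len(out) < n:
        batch = min(n - len(out) + 16, limit - tries)
        if batch <= 0:
            raise SpacerSpaceExhausted(
                f"placed {len(out)}/{n} spacers after {tries} draws"
            )
        tries += batch
        chunk = _BASES[rng.integers(0, 4, size=(batch, SPACER_LEN))]
        for cand in ("".join(row) for row in chunk):
            if len(out) == n:
                break
            if cand in taken or cand in forbidden:
                continue
            out.append(cand)
            taken.add(cand)
            if min_distance >= 2:
                forbidden.add(cand)
                for i in range(SPACER_LEN):
                    for b in "ACGT":
                        if b != cand[i]:
                            forbidden.add(cand[:i] + b + cand[i + 1:])
    return out


def simulate_library(
    config: SimConfig,
    gene_names: list[str] | None = None,
    class_overrides: dict[str, str] | None = None,
    active_overrides: dict[str, list[bool]] | None = None,
    min_spacer_distance: int = 2,
) -> tuple[LibraryDesign, SimTruth]:
    """Build a synthetic library and its ground truth.

    Gene classes are independent draws (effector_fraction / inhibitor_fraction
    / remainder null); guide activity is an independent Bernoulli draw with
    sgrna_active_prob. ``class_overrides`` pins named genes to a class and
    ``active_overrides`` pins their per-guide active flags — used to spike in
    genes with a known configuration.
    """
    if gene_names is None:
        gene_names = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    if len(gene_names) != config.n_genes or len(set(gene_names)) != config.n_genes:
        raise ValueError("gene_names must be n_genes unique names")
    if NTC_TOKEN in gene_names:
        raise ValueError(f"{NTC_TOKEN!r} is reserved for nontargeting controls")

    rng_cls = _stream(config.seed, _STREAM_CLASSES)
    draws = rng_cls.random(config.n_genes)
    klass = np.where(
        draws < config.effector_fraction, EFFECTOR,
        np.where(draws < config.effector_fraction + config.inhibitor_fraction,
                 INHIBITOR, NULL),
    ).astype(object)
    genes = pd.DataFrame({"klass": klass}, index=pd.Index(gene_names, name="gene"))
    for g, k in (class_overrides or {}).items():
        if g not in genes.index:
            raise ValueError(f"override for unknown gene {g!r}")
        if k not in (EFFECTOR, INHIBITOR, NULL):
            raise ValueError(f"unknown class {k!r}")
        genes.loc[g, "klass"] = k
    genes["effect_fold"] = np.where(genes["klass"] == NULL, 1.0, config.effect_fold)

    rows = []
    for g in gene_names:
        for j in range(1, config.sgrnas_per_gene + 1):
            rows.append((f"{g}_sg{j}", g))
    for j in range(1, config.n_ntc + 1):
        rows.append((f"{NTC_TOKEN}_sg{j:03d}", NTC_TOKEN))
    ids = pd.DataFrame(rows, columns=["sgrna_id", "gene"])

    rng_sp = _stream(config.seed, _STREAM_SPACERS)
    ids["spacer"] = _random_spacers(len(ids), rng_sp, min_spacer_distance)
    library = LibraryDesign(ids)

    rng_act = _stream(config.seed, _STREAM_ACTIVE)
    active = rng_act.random(len(ids)) < config.sgrna_active_prob
    sgr = pd.DataFrame(
        {"gene": ids["gene"].to_numpy(), "active": active},
        index=pd.Index(ids["sgrna_id"], name="sgrna_id"),
    )
    sgr.loc[sgr["gene"] == NTC_TOKEN, "active"] = False
    for g, flags in (active_overrides or {}).items():
        members = sgr.index[sgr["gene"] == g]
        if len(members) != len(flags):
            raise ValueError(
                f"active_overrides[{g!r}] has {len(flags)} flags for "
                f"{len(members)} guides"
            )
        sgr.loc[members, "active"] = list(flags)
    return library, SimTruth(genes, sgr)


def simulate_counts(
    library: LibraryDesign, truth: SimTruth, config: SimConfig
) -> CountMatrix:
    """Draw an sgRNA x sample count matrix under the generative model.

    Samples are named ``{condition}_r{replicate}`` for the three conditions
    input / empty / yap and replicates 1..n_replicates.
    """
    ids = library.sgrna_ids
    n = len(ids)
    if n == 0:
        raise ValueError("empty library")
    sgr = truth.sgrnas.loc[ids]
    gene_class = truth.genes["klass"].reindex(sgr["gene"]).fillna(NULL).to_numpy()
    gene_fold = truth.genes["effect_fold"].reindex(sgr["gene"]).fillna(1.0).to_numpy()
    sign = np.where(gene_class == EFFECTOR, 1.0,
                    np.where(gene_class == INHIBITOR, -1.0, 0.0))
    fold = gene_fold ** (sign * sgr["active"].to_numpy())

    cols: dict[str, np.ndarray] = {}
    meta = []
    for r in range(1, config.n_replicates + 1):
        rng_base = _stream(config.seed, _STREAM_BASE, r)
        base = rng_base.lognormal(0.0, config.library_skew_sd, n)
        drift_empty = rng_base.lognormal(0.0, config.drift_sd, n)
        drift_yap = rng_base.lognormal(0.0, config.drift_sd, n)
        abundances = {
            "input": base,
            "empty": base * drift_empty,
            "yap": base * drift_yap * fold,
        }
        for ci, cond in enumerate(CONDITIONS):
            abund = abundances[cond]
            total = abund.sum()
            if total <= 0:
                raise ValueError(f"degenerate configuration: zero total abundance "
                                 f"in {cond} replicate {r}")
            rel = abund / total
            rng_s = _stream(config.seed, _STREAM_SAMPLES, ci, r)
            sigma = config.baseline_dispersion
            eps = rng_s.lognormal(-0.5 * sigma * sigma, sigma, n) if sigma > 0 else 1.0
            lam = config.mean_depth * n * rel * eps
            sample_id = f"{cond}_r{r}"
            cols[sample_id] = rng_s.poisson(lam)
            meta.append((sample_id, cond, r))
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="sgrna_id"))
    samples = pd.DataFrame(
        meta, columns=["sample_id", "condition", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(counts, samples)


def simulate_screen(config: SimConfig, **library_kwargs):
    """Convenience wrapper: (library, truth, counts) in one call."""
    library, truth = simulate_library(config, **library_kwargs)
    return library, truth, simulate_counts(library, truth, config)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

# First bases of the constant sgRNA scaffold, appended after the spacer so
# emitted reads are longer than the spacer itself (26-nt reads).
_SCAFFOLD_PAD = "GTTTTA"


def write_fixture(
    library: LibraryDesign,
    counts: CountMatrix,
    truth: SimTruth | None,
    out_dir: str | Path,
    emit_fastq: bool = False,
    header: str = "",
) -> dict[str, Path]:
    """Write library / counts / sample sheet / truth (and optional FASTQs).

    FASTQ reads start with the guide's spacer and repeat it exactly as many
    times as its count-matrix entry, so exact-match re-quantification must
    reproduce the matrix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["library"] = out_dir / "library.tsv"
    write_library(library, files["library"], header)
    files["counts"] = out_dir / "counts.tsv"
    files["samples"] = out_dir / "samples.tsv"
    write_counts(counts, files["counts"], files["samples"], header)
    if truth is not None:
        files["truth"] = out_dir / "truth.tsv"
        from .quantify import _write_table

        _write_table(truth.to_frame(), files["truth"], header)

    if emit_fastq:
        spacer_of = dict(zip(library.table["sgrna_id"], library.table["spacer"]))
        for sample_id in counts.counts.columns:
            path = out_dir / f"{sample_id}.fastq"
            with open(path, "w") as fh:
                i = 0
                for sid, k in counts.counts[sample_id].items():
                    seq = spacer_of[sid] + _SCAFFOLD_PAD
                    qual = "I" * len(seq)
                    for _ in range(int(k)):
                        i += 1
                        fh.write(f"@{sample_id}:{i}\n{seq}\n+\n{qual}\n")
            files[f"fastq:{sample_id}"] = path
    return files
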