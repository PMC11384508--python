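import numpy as np
import pandas as pd
import pytest

from rescuescreen import CountMatrix, LibraryDesign, SimConfig, simulate_screen


@pytest.fixture
def toy_library() -> LibraryDesign:
    return LibraryDesign(pd.DataFrame({
        "sgrna_id": ["A_sg1", "A_sg2", "NTC_sg001"],
        "gene": ["A", "A", "NTC"],
        "spacer": [
            "GACCGGAACGATCTCGCGTA",   # published control spacer
            "ACATGGTGGATAGATAGCCA",
            "CCAGAACGACCACGTCACAC",
        ],
    }))


def make_count_matrix(counts: dict[str, list[int]],
                      sgrna_ids: list[str]) -> CountMatrix:
    """Build a CountMatrix from per-sample count lists; sample ids follow the
    pipeline's {condition}_r{replicate} convention."""
    frame = pd.DataFrame(counts, index=pd.Index(sgrna_ids, name="sgrna_id"))
    meta = []
    for sid in frame.columns:
        cond, rep = sid.rsplit("_r", 1)
        meta.append((sid, cond, int(rep)))
    samples = pd.DataFrame(meta, columns=["sample_id", "condition", "replicate"]
                           ).set_index("sample_id")
    return CountMatrix(frame, samples)


@pytest.fixture
def small_screen():
    """A compact simulated screen with a few true hits (fixed seed)."""
    config = SimConfig(n_genes=30, sgrnas_per_gene=4, n_ntc=12,
                       effector_fraction=0.1, inhibitor_fraction=0.1,
                       mean_depth=300, seed=42)
    library, truth, counts = simulate_screen(config)
    return config, library, truth, counts


def random_count_matrix(rng: np.random.Generator, n_sgrnas: int,
                        n_replicates: int = 3,
                        n_ntc: int = 6) -> tuple[LibraryDesign, CountMatrix]:
    """Random small library + counts for oracle-equivalence checks."""
    from rescuescreen.quantify import NTC_TOKEN

    bases = np.array(list("ACGT"))
    n_targeted = n_sgrnas - n_ntc
    ids, genes = [], []
    for i in range(n_targeted):
        ids.append(f"G{i // 2:03d}_sg{i % 2 + 1}")
        genes.append(f"G{i // 2:03d}")
    for j in range(n_ntc):
        ids.append(f"NTC_sg{j:03d}")
        genes.append(NTC_TOKEN)
    spacers = set()
    while len(spacers) < n_sgrnas:
        spacers.add("".join(rng.choice(bases, 20)))
    library = LibraryDesign(pd.DataFrame(
        {"sgrna_id": ids, "gene": genes, "spacer": sorted(spacers)}))
    counts = {}
    for rep in range(1, n_replicates + 1):
        for cond in ("input", "empty", "yap"):
            counts[f"{cond}_r{rep}"] = rng.integers(0, 400, n_sgrnas)
    return library, make_count_matrix(counts, ids)
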