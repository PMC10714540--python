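import numpy as np
import pandas as pd
import pytest

from metadomain.synthetic import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic bundle shared across tests."""
    return generate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """A minimal two-family bundle for fast structural checks."""
    return generate_bundle(SimulationConfig(
        seed=3, n_families=2, members_per_family=3, domain_length=30,
        n_singleton_genes=1, n_pathogenic=20, n_benign=20,
        selection_multipliers=(1.0, 0.2)))


def random_toy_dataset(rng: np.random.Generator, n_variants: int = 25):
    """A small labelled-variant table plus a residue->meta-position mapping.

    Variants are scattered over a few proteins and residues so that
    co-localisation, conflicts and meta-position sharing all occur by chance.
    """
    proteins = [f"P{i}" for i in range(1, 1 + rng.integers(3, 6))]
    aas = list("ACDEFGHIKL")
    rows = []
    seen = set()
    while len(rows) < n_variants:
        prot = proteins[rng.integers(len(proteins))]
        residue = int(rng.integers(1, 9))
        ref_aa = aas[rng.integers(len(aas))]
        alt_aa = aas[rng.integers(len(aas))]
        if ref_aa == alt_aa:
            continue
        key = (prot, residue, ref_aa, alt_aa)
        if key in seen:
            continue
        seen.add(key)
        rows.append({
            "chrom": "chr1", "pos": len(rows) * 10 + 1, "ref": "A", "alt": "C",
            "protein_id": prot, "residue_index": residue,
            "ref_aa": ref_aa, "alt_aa": alt_aa,
            "label": "pathogenic" if rng.random() < 0.55 else "benign",
        })
    dataset = pd.DataFrame(rows)
    # map ~70% of (protein, residue) positions into one shared family so
    # distinct proteins collide at meta-positions
    positions = dataset[["protein_id", "residue_index"]].drop_duplicates()
    map_rows = []
    for _, p in positions.iterrows():
        if rng.random() < 0.7:
            map_rows.append({
                "protein_id": p["protein_id"],
                "residue_index": p["residue_index"],
                "family_id": "FAM1",
                "column_label": str(int(rng.integers(1, 6))),
                "is_insertion": False,
            })
    mapping = pd.DataFrame(
        map_rows, columns=["protein_id", "residue_index", "family_id",
                           "column_label", "is_insertion"])
    return dataset, mapping
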