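"""Seed-reproducible synthetic inputs for every pipeline stage.

The generator emulates the input classes the pipeline consumes in the wild:

* a small genome with protein-coding genes on both strands, multi-exon
  transcripts and codons spanning exon junctions;
* paralogous domain families shared across genes, emitted as Stockholm
  alignments with substitutions, insertions (lowercase/'.') and deletions
  ('-') so the column-numbering rules are exercised;
* population variation generated per possible SNV as a Bernoulli site
  observation, with a per-family *selection multiplier* ``s`` scaling the
  probability that a possible missense SNV is seen (s = 1: neutral; s << 1:
  strong missense constraint) — the closed-form expectation of the
  per-position adjusted m/s score under this model is ``s`` itself;
* ClinVar-style assertions placed on missense SNVs with a tunable probability
  of clustering at already-labelled meta-positions, plus REVEL-like scores
  drawn high for pathogenic and low for benign variants.

Identical (seed, config) always produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metadomain import transcripts as tm
from metadomain.alignments import map_residues, parse_stockholm

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(tm.GENETIC_CODE.items()):
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
STOP_CODONS = _CODONS_FOR_AA["*"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Probabilities are per-event; ``mutation_rate`` is the per-possible-SNV
    probability that the site is observed in the population sample, and the
    per-family ``selection_multipliers`` scale that probability for missense
    SNVs inside the family's domain instances.  ``meta_cluster_weight`` is the
    probability that a new clinical label is placed at an already-labelled
    meta-position rather than uniformly.
    """

    seed: int = 0
    n_families: int = 6
    members_per_family: int = 3
    domain_length: int = 40
    n_singleton_genes: int = 2
    flank_length_range: tuple[int, int] = (5, 15)
    exon_length_range: tuple[int, int] = (45, 120)
    insertion_rate: float = 0.02
    deletion_rate: float = 0.02
    substitution_rate: float = 0.3
    mutation_rate: float = 0.3
    selection_multipliers: tuple[float, ...] = (1.0, 0.7, 0.5, 0.3, 0.15, 0.05)
    n_pathogenic: int = 60
    n_benign: int = 60
    meta_cluster_weight: float = 0.6
    colocal_same_residue_weight: float = 0.3
    benign_out_of_domain_frac: float = 0.5
    revel_scored_frac: float = 0.9
    nonpass_frac: float = 0.03
    allele_number: int = 152000

    def validate(self) -> None:
        for name in ("insertion_rate", "deletion_rate", "substitution_rate",
                     "mutation_rate", "meta_cluster_weight",
                     "colocal_same_residue_weight", "benign_out_of_domain_frac",
                     "revel_scored_frac", "nonpass_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_families", "members_per_family", "domain_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_singleton_genes < 0 or self.n_pathogenic < 0 or self.n_benign < 0:
            raise ValueError("counts must be non-negative")
        for s in self.selection_multipliers:
            if not 0.0 < s <= 1.0:
                raise ValueError(f"selection multipliers must lie in (0, 1], got {s}")
        if self.flank_length_range[0] < 1:
            raise ValueError("flanks must hold at least one residue so the domain fits")

    def family_multiplier(self, family_index: int) -> float:
        return self.selection_multipliers[family_index % len(self.selection_multipliers)]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("flank_length_range", "exon_length_range", "selection_multipliers"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Bundle:
    """In-memory synthetic inputs plus the generating truth."""

    config: SimulationConfig
    genome: dict[str, str]
    exon_table: pd.DataFrame
    proteins: dict[str, str]
    stockholm: str
    population: pd.DataFrame
    clinical: pd.DataFrame
    revel: pd.DataFrame
    truth_families: pd.DataFrame
    truth_variants: pd.DataFrame
    transcripts: list = field(default_factory=list)


def expected_adjusted_ms(config: SimulationConfig, family_index: int) -> float:
    """Closed-form expectation of the per-position adjusted m/s score.

    Under the generator's model each possible missense SNV in family ``f`` is
    observed with probability ``s_f * mu`` and each synonymous SNV with
    ``mu``, so every per-position obs/poss ratio has expectation ``s_f * mu``
    (missense) or ``mu`` (synonymous) and the score's expectation is ``s_f``.
    """
    return config.family_multiplier(family_index)


# ---------------------------------------------------------------------------
# generation


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _cds_for_protein(rng: np.random.Generator, protein: str) -> str:
    codons = [
        _CODONS_FOR_AA[aa][rng.integers(len(_CODONS_FOR_AA[aa]))] for aa in protein
    ]
    codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def _make_family(rng: np.random.Generator, cfg: SimulationConfig, fam_idx: int,
                 protein_ids: list[str]) -> dict:
    """Simulate one domain family: per-member residues plus alignment states.

    Returns per-member lists of (column_kind, letter) where column_kind is a
    match-column index or an insertion slot, from which both the domain
    residue string and the Stockholm row are later assembled.
    """
    L = cfg.domain_length
    consensus = _random_protein(rng, L)
    members = []
    for pid in protein_ids:
        states: list[tuple[int, int, str]] = []  # (match_col, insert_ord, letter or '-')
        # insertions may precede the first match column (slot 0)
        for col in range(L + 1):
            if col > 0:
                if rng.random() < cfg.deletion_rate:
                    states.append((col, 0, "-"))
                else:
                    letter = consensus[col - 1]
                    if rng.random() < cfg.substitution_rate:
                        letter = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                    states.append((col, 0, letter))
            if rng.random() < cfg.insertion_rate:
                for j in range(1, int(rng.integers(1, 3)) + 1):
                    states.append((col, j, AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))].lower()))
        # reorder: states were appended match-then-insertions per column slot,
        # but insertions after column c must follow the column-c match state
        states.sort(key=lambda t: (t[0], 0 if t[2] == "-" or t[2].isupper() else 1, t[1]))
        members.append({"protein_id": pid, "states": states})
    return {"family_id": f"FAM{fam_idx + 1:03d}", "consensus": consensus, "members": members}


def _member_residues(states) -> str:
    return "".join(c for _, _, c in states if c != "-").upper()


def _stockholm_block(family: dict, domain_coords: dict[str, tuple[int, int]]) -> str:
    """Render one family as a Stockholm alignment with global insert columns."""
    L = max(col for m in family["members"] for col, _, _ in m["states"])
    max_ins = {col: 0 for col in range(L + 1)}
    for m in family["members"]:
        for col, j, c in m["states"]:
            if c.islower():
                max_ins[col] = max(max_ins[col], j)
    lines = ["# STOCKHOLM 1.0", f"#=GF AC {family['family_id']}"]
    for m in family["members"]:
        by_slot: dict[tuple[int, int], str] = {}
        for col, j, c in m["states"]:
            by_slot[(col, j)] = c
        row = []
        for col in range(L + 1):
            if col > 0:
                row.append(by_slot.get((col, 0), "-"))
            for j in range(1, max_ins[col] + 1):
                row.append(by_slot.get((col, j), "."))
        start, end = domain_coords[m["protein_id"]]
        name = f"{m['protein_id']}/{start}-{end}"
        lines.append(f"{name:<24s} {''.join(row)}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def _split_exons(rng: np.random.Generator, cfg: SimulationConfig, cds_len: int,
                 force_junction_codon: bool) -> list[int]:
    """Chunk a CDS into exon lengths within the configured range."""
    lo, hi = cfg.exon_length_range
    lengths: list[int] = []
    remaining = cds_len
    while remaining > hi:
        take = int(rng.integers(lo, hi + 1))
        lengths.append(take)
        remaining -= take
    lengths.append(remaining)
    if force_junction_codon and len(lengths) > 1 and lengths[0] % 3 == 0:
        lengths[0] += 1
        lengths[1] -= 1
    return [l for l in lengths if l > 0]


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Generate the full synthetic input bundle in memory."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- gene/protein layout -------------------------------------------------
    genes = []  # dicts: gene_id, protein_id, family (or None), domain span
    families = []
    gene_counter = 0
    for f in range(cfg.n_families):
        pids = []
        for m in range(cfg.members_per_family):
            gene_counter += 1
            pids.append(f"PROT{gene_counter:03d}")
        fam = _make_family(rng, cfg, f, pids)
        families.append(fam)
        for m, pid in enumerate(pids):
            genes.append({
                "gene_id": f"GENE{gene_counter - cfg.members_per_family + m + 1:03d}",
                "protein_id": pid, "family": fam, "member_index": m,
            })
    for s in range(cfg.n_singleton_genes):
        gene_counter += 1
        genes.append({
            "gene_id": f"GENE{gene_counter:03d}",
            "protein_id": f"PROT{gene_counter:03d}", "family": None,
        })

    proteins: dict[str, str] = {}
    domain_coords: dict[str, tuple[int, int]] = {}
    for g in genes:
        n_flank = int(rng.integers(cfg.flank_length_range[0], cfg.flank_length_range[1] + 1))
        c_flank = int(rng.integers(cfg.flank_length_range[0], cfg.flank_length_range[1] + 1))
        if g["family"] is not None:
            member = g["family"]["members"][g["member_index"]]
            dom = _member_residues(member["states"])
            prot = _random_protein(rng, n_flank) + dom + _random_protein(rng, c_flank)
            domain_coords[g["protein_id"]] = (n_flank + 1, n_flank + len(dom))
        else:
            prot = _random_protein(rng, n_flank + c_flank + 10)
        proteins[g["protein_id"]] = prot

    # --- genome assembly -----------------------------------------------------
    chrom = "chr1"
    genome_parts: list[str] = []
    pos = 0
    exon_rows = []
    for gi, g in enumerate(genes):
        strand = "+" if gi % 2 == 0 else "-"
        cds = _cds_for_protein(rng, proteins[g["protein_id"]])
        chunk_lengths = _split_exons(rng, cfg, len(cds), force_junction_codon=(gi == 0))
        chunks, off = [], 0
        for ln in chunk_lengths:
            chunks.append(cds[off: off + ln])
            off += ln
        spacer = _random_dna(rng, int(rng.integers(20, 51)))
        genome_parts.append(spacer)
        pos += len(spacer)
        placed = []
        order = chunks if strand == "+" else list(reversed(chunks))
        for ci, chunk in enumerate(order):
            if ci > 0:
                intron = _random_dna(rng, int(rng.integers(10, 31)))
                genome_parts.append(intron)
                pos += len(intron)
            seq = chunk if strand == "+" else tm.reverse_complement(chunk)
            genome_parts.append(seq)
            placed.append((pos + 1, pos + len(seq)))
            pos += len(seq)
        exons = placed if strand == "+" else list(reversed(placed))
        for rank, (start, end) in enumerate(exons, start=1):
            exon_rows.append((g["gene_id"], g["gene_id"].replace("GENE", "TRANS"),
                              g["protein_id"], chrom, strand, start, end, rank))
        g["strand"] = strand
    genome = {chrom: "".join(genome_parts)}
    exon_table = pd.DataFrame(exon_rows, columns=[
        "gene_id", "transcript_id", "protein_id", "chrom", "strand",
        "exon_start", "exon_end", "exon_rank"])

    # --- transcripts and SNV universe ---------------------------------------
    transcripts = tm.load_transcripts(exon_table, genome)
    if len(transcripts) != len(genes):
        raise AssertionError("generator emitted an invalid transcript")
    for t in transcripts:
        if proteins[t.protein_id] != t.protein_sequence:
            raise AssertionError(f"CDS/protein mismatch for {t.protein_id}")
    universe = tm.simulate_all_snvs(transcripts)

    stockholm = "".join(_stockholm_block(f, domain_coords) for f in families)
    mapping = map_residues(parse_stockholm(stockholm), proteins)

    # --- population observations ---------------------------------------------
    fam_of_protein = {}
    for f_idx, fam in enumerate(families):
        for m in fam["members"]:
            fam_of_protein[m["protein_id"]] = f_idx
    in_dom = pd.Series(False, index=universe.index)
    dom_fam = pd.Series(-1, index=universe.index)
    for pid, (dstart, dend) in domain_coords.items():
        mask = ((universe["protein_id"] == pid)
                & (universe["residue_index"] >= dstart)
                & (universe["residue_index"] <= dend))
        in_dom |= mask
        dom_fam[mask] = fam_of_protein[pid]
    p_obs = np.full(len(universe), cfg.mutation_rate)
    missense = (universe["consequence"] == "missense").to_numpy()
    for f_idx in range(cfg.n_families):
        sel = missense & (dom_fam == f_idx).to_numpy()
        p_obs[sel] *= cfg.family_multiplier(f_idx)
    p_obs[(universe["consequence"] == "other").to_numpy()] = 0.0
    observed = rng.random(len(universe)) < p_obs
    pop = universe.loc[observed, ["chrom", "pos", "ref", "alt"]].copy()
    pop["AC"] = rng.integers(1, 6, size=len(pop))
    pop["AN"] = cfg.allele_number
    nonpass = rng.random(len(pop)) < cfg.nonpass_frac
    pop["filter"] = np.where(nonpass, "AC0", "PASS")
    population = pop.reset_index(drop=True)

    # --- clinical assertions --------------------------------------------------
    fam_s = {fam["family_id"]: cfg.family_multiplier(i) for i, fam in enumerate(families)}
    clinical, truth_variants = _place_clinical(rng, cfg, universe, mapping, fam_s)

    # --- REVEL-like scores ----------------------------------------------------
    revel_rows = []
    for _, row in truth_variants.iterrows():
        if rng.random() > cfg.revel_scored_frac:
            continue
        if row["label"] == "pathogenic":
            score = rng.beta(8, 2)
        else:
            score = rng.beta(2, 8)
        revel_rows.append((row["chrom"], row["pos"], row["ref_aa"], row["alt_aa"],
                           round(float(score), 3)))
    revel = pd.DataFrame(revel_rows, columns=["chrom", "pos", "ref_aa", "alt_aa", "revel"])
    revel = revel.drop_duplicates(subset=["chrom", "pos", "ref_aa", "alt_aa"])

    truth_families = pd.DataFrame({
        "family_id": [f["family_id"] for f in families],
        "selection_multiplier": [cfg.family_multiplier(i) for i in range(cfg.n_families)],
    })

    return Bundle(
        config=cfg, genome=genome, exon_table=exon_table, proteins=proteins,
        stockholm=stockholm, population=population, clinical=clinical,
        revel=revel, truth_families=truth_families, truth_variants=truth_variants,
        transcripts=transcripts,
    )


def _place_clinical(rng, cfg, universe, mapping, fam_s: dict[str, float]):
    """Place pathogenic/benign labels on missense SNVs with meta clustering.

    In-domain placements are weighted by the family's selection multiplier:
    pathogenic labels favour constrained families (small ``s``) and benign
    labels tolerant ones, emulating the clustering of pathogenic variation in
    constrained domains that makes domain-level constraint informative.
    """
    mis = universe[universe["consequence"] == "missense"].reset_index(drop=True)
    mis = mis.merge(
        mapping[["protein_id", "residue_index", "family_id", "column_label"]],
        on=["protein_id", "residue_index"], how="left")
    mis["meta_id"] = np.where(
        mis["family_id"].notna(), mis["family_id"].astype(str) + ":" + mis["column_label"].astype(str), "")
    in_dom_idx = mis.index[mis["meta_id"] != ""].to_numpy()
    out_dom_idx = mis.index[mis["meta_id"] == ""].to_numpy()
    meta_groups = {k: v.to_numpy() for k, v in mis.groupby("meta_id").groups.items() if k}
    res_groups = {k: v.to_numpy() for k, v in
                  mis.groupby(["protein_id", "residue_index"]).groups.items()}
    fam_ids = sorted(fam_s)
    fam_groups = {f: mis.index[mis["family_id"] == f].to_numpy() for f in fam_ids}
    # pathogenic labels concentrate in constrained families (small s), benign
    # labels are strongly depleted from them; the quadratic benign weight
    # mirrors how rarely tolerated variation reaches constrained domains
    eps = 0.02
    w_path = np.array([1.0 + eps - fam_s[f] for f in fam_ids])
    w_ben = np.array([fam_s[f] ** 2 + eps for f in fam_ids])
    fam_weights = {"pathogenic": w_path / w_path.sum(), "benign": w_ben / w_ben.sum()}

    used: set[int] = set()
    chosen: list[tuple[int, str]] = []
    labelled_metas: dict[str, list[int]] = {"pathogenic": [], "benign": []}
    labelled_rows: dict[str, list[int]] = {"pathogenic": [], "benign": []}
    meta_keys: dict[str, list[str]] = {"pathogenic": [], "benign": []}

    def pick(pool: np.ndarray) -> int | None:
        pool = pool[~np.isin(pool, list(used))] if used else pool
        if len(pool) == 0:
            return None
        return int(pool[rng.integers(len(pool))])

    def pick_cluster_key(label: str) -> str:
        # keep clustered placements under the same family enrichment as fresh ones
        keys = meta_keys[label]
        w = np.array([fam_weights[label][fam_ids.index(k.split(":")[0])] for k in keys])
        return keys[rng.choice(len(keys), p=w / w.sum())]

    def place(label: str, n: int, out_frac: float) -> None:
        for _ in range(n):
            idx = None
            if rng.random() < out_frac and len(out_dom_idx):
                idx = pick(out_dom_idx)
            if idx is None and meta_keys[label] and rng.random() < cfg.meta_cluster_weight:
                if labelled_rows[label] and rng.random() < cfg.colocal_same_residue_weight:
                    prev = mis.loc[labelled_rows[label][rng.integers(len(labelled_rows[label]))]]
                    idx = pick(res_groups[(prev["protein_id"], prev["residue_index"])])
                if idx is None:
                    idx = pick(meta_groups[pick_cluster_key(label)])
            if idx is None and fam_ids:
                fam = fam_ids[rng.choice(len(fam_ids), p=fam_weights[label])]
                idx = pick(fam_groups[fam])
            if idx is None:
                idx = pick(in_dom_idx)
            if idx is None:
                idx = pick(np.arange(len(mis)))
            if idx is None:
                break
            used.add(idx)
            chosen.append((idx, label))
            labelled_rows[label].append(idx)
            mid = mis.loc[idx, "meta_id"]
            if mid and mid not in meta_keys[label]:
                meta_keys[label].append(mid)

    place("pathogenic", cfg.n_pathogenic, out_frac=0.0)
    place("benign", cfg.n_benign, out_frac=cfg.benign_out_of_domain_frac)

    rows = []
    for idx, label in chosen:
        r = mis.loc[idx]
        if label == "pathogenic":
            classification = "P" if rng.random() < 0.5 else "LP"
        else:
            classification = "B" if rng.random() < 0.5 else "LB"
        rows.append((r["chrom"], r["pos"], r["ref"], r["alt"], classification,
                     label, r["protein_id"], r["residue_index"], r["ref_aa"],
                     r["alt_aa"], r["meta_id"]))
    truth = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "classification", "label", "protein_id",
        "residue_index", "ref_aa", "alt_aa", "meta_id"])
    truth = truth.sort_values(["pos", "alt"]).reset_index(drop=True)
    clinical = truth[["chrom", "pos", "ref", "alt", "classification"]].copy()
    return clinical, truth


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# writing


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_bundle(bundle: Bundle, outdir) -> dict[str, Path]:
    """Write the bundle in the exact text formats the pipeline ingests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "proteins": outdir / "proteins.fa",
        "exons": outdir / "exons.tsv",
        "stockholm": outdir / "domains.sto",
        "population": outdir / "population.tsv",
        "clinical": outdir / "clinical.tsv",
        "revel": outdir / "revel.tsv",
        "truth_families": outdir / "truth_families.tsv",
        "truth_variants": outdir / "truth_variants.tsv",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_fasta(bundle.proteins, paths["proteins"])
    bundle.exon_table.to_csv(paths["exons"], sep="\t", index=False)
    paths["stockholm"].write_text(bundle.stockholm)
    bundle.population.to_csv(paths["population"], sep="\t", index=False)
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    bundle.revel.to_csv(paths["revel"], sep="\t", index=False)
    bundle.truth_families.to_csv(paths["truth_families"], sep="\t", index=False)
    bundle.truth_variants.to_csv(paths["truth_variants"], sep="\t", index=False)
    return paths


def generate(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write the file bundle; returns the emitted paths."""
    return write_bundle(generate_bundle(config), outdir)
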