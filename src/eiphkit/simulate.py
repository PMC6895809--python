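"""Synthetic cohort generator for the EIPH analysis pipeline.

Generates every input the pipeline reads — genotypes with LD-block and
half-sib family structure, gene annotations with overlapping function
tags, causal-SNP phenotypes, weekly tracheal-wash cytology series and
race records — with the statistical structure the analysis assumes, so
every stage is testable without external data.

Study-condition defaults: 72 horses (32 male, 40 female), three
half-sib families of 8 on a common background, ~1 SNP per 43.2 kb on 31
chromosomes, function-tag gene sets of sizes 43/50/26/33/29/258 with a
5-gene triple intersection, and causal SNPs planted inside
cytoskeleton- and blood-flow-tagged genes.

Genotypes: haplotypes are drawn from a latent Gaussian AR(1) process
within LD blocks, thresholded at MAF-matched quantiles.  Each half-sib
offspring receives one unrecombined sire haplotype plus one population
haplotype, which reproduces the outlying-family-cluster phenomenology
in MDS space.

Cytology: weekly bleeding events are Bernoulli with probability
increasing in the horse's genetic risk score; haemosiderophage scores
rise to 2-3 for the one-to-three weeks after an event and decay back to
0-1, mimicking the known kinetics of haemosiderophage appearance after
haemorrhage.  Other cytology categories are i.i.d. noise (they are
pipeline pass-through).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .cytology import CATEGORIES
from .genio import MAP_COLUMNS, GenotypeMatrix

SET_SIZES = {  # genes per function tag, at study scale
    "cell_cell_adhesion": 43, "cytoskeleton": 50, "blood_flow": 26,
    "stroke": 33, "hypertension": 29, "random": 258,
}
#: multi-tag membership: (tags) -> number of genes carrying exactly those tags
INTERSECTION_SCHEME = {
    ("cell_cell_adhesion", "cytoskeleton", "blood_flow"): 5,
    ("cytoskeleton", "blood_flow"): 4,       # 9 total incl. the triple
    ("cell_cell_adhesion", "blood_flow"): 9,  # 14 total incl. the triple
    ("cell_cell_adhesion", "cytoskeleton"): 6,  # 11 total incl. the triple
}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_individuals: int = 72
    n_male: int = 32
    n_families: int = 3
    family_size: int = 8
    n_snps: int = 20_000
    n_chromosomes: int = 31
    snp_spacing_bp: int = 43_200
    ld_block_len: int = 20
    within_block_rho: float = 0.8
    maf_min: float = 0.05
    maf_max: float = 0.5
    missing_rate: float = 0.0
    set_sizes: dict = field(default_factory=lambda: dict(SET_SIZES))
    intersections: dict = field(default_factory=lambda: dict(INTERSECTION_SCHEME))
    gene_min_span_snps: int = 2
    gene_max_span_snps: int = 5
    causal_sets: tuple = ("cytoskeleton", "blood_flow")
    n_causal_per_set: int = 2
    effect_size: float | None = None    # None = unit effects, rescaled via h2
    h2: float = 0.7
    bleed_intercept: float = -2.2       # logit weekly bleed probability at mean risk
    bleed_slope: float = 0.9            # logit increase per SD of genetic risk
    n_weeks_per_season: int = 36        # March-November weekly sampling
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must be in [0, 1)")
        if self.n_families * self.family_size > self.n_individuals:
            raise ValueError("families larger than the cohort")


NUCLEOTIDES = np.array(["A", "C", "G", "T"])


def _draw_haplotypes(rng, n_hap: int, mafs: np.ndarray, block_len: int,
                     rho: float) -> np.ndarray:
    """0/1 haplotypes from a blockwise latent Gaussian AR(1), thresholded at MAF quantiles."""
    m = mafs.size
    z = np.empty((n_hap, m))
    start = 0
    while start < m:
        stop = min(start + block_len, m)
        z[:, start] = rng.standard_normal(n_hap)
        for j in range(start + 1, stop):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_hap)
        start = stop
    thresh = stats.norm.ppf(mafs)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_genotypes(config: SimConfig, rng=None):
    """Genotypes + SNP map + family labels for the configured cohort.

    Returns (GenotypeMatrix, families) where ``families`` labels each
    individual 0 for the unrelated background or 1..n_families for the
    half-sib cluster it belongs to.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_snps
    mafs = rng.uniform(config.maf_min, config.maf_max, size=m)

    n = config.n_individuals
    n_fam_members = config.n_families * config.family_size
    families = np.zeros(n, dtype=int)
    for f in range(config.n_families):
        families[f * config.family_size:(f + 1) * config.family_size] = f + 1

    # population haplotypes: 2 per unrelated individual, 1 (dam side) per
    # half-sib + 2 per sire
    n_pop_haps = 2 * (n - n_fam_members) + n_fam_members + 2 * config.n_families
    haps = _draw_haplotypes(rng, n_pop_haps, mafs, config.ld_block_len,
                            config.within_block_rho)
    calls = np.empty((n, m), dtype=float)
    cursor = 0
    sire_haps = []
    for f in range(config.n_families):
        sire_haps.append(haps[cursor:cursor + 2])
        cursor += 2
    for i in range(n):
        if families[i] > 0:
            sire = sire_haps[families[i] - 1]
            paternal = sire[rng.integers(2)]
            maternal = haps[cursor]
            cursor += 1
        else:
            paternal = haps[cursor]
            maternal = haps[cursor + 1]
            cursor += 2
        calls[i] = paternal + maternal

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = np.nan

    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chroms, positions = [], []
    for j in range(m):
        c = j // per_chrom + 1
        chroms.append(c)
        positions.append((j % per_chrom + 1) * config.snp_spacing_bp)
    allele_pairs = np.stack([
        rng.permutation(4)[:2] for _ in range(m)
    ])
    # code dosages against the sample minor allele (ties lexicographic),
    # matching the PED reader's convention so write->read round-trips
    a = NUCLEOTIDES[allele_pairs[:, 0]].astype(object)
    b = NUCLEOTIDES[allele_pairs[:, 1]].astype(object)
    count_a = np.nansum(calls, axis=0)
    n_nonmiss = np.sum(~np.isnan(calls), axis=0)
    count_b = 2 * n_nonmiss - count_a
    flip = (count_a > count_b) | ((count_a == count_b) & (a > b))
    calls[:, flip] = 2.0 - calls[:, flip]
    a[flip], b[flip] = b[flip], a[flip]
    allele_pairs = None  # labels now live in a/b
    snp_map = pd.DataFrame({
        "snp_id": [f"SNP{j:06d}" for j in range(m)],
        "chromosome": chroms,
        "position": positions,
        "allele_a": a,
        "allele_b": b,
    })[MAP_COLUMNS]

    sexes = np.array(["M"] * config.n_male + ["F"] * (n - config.n_male), dtype=object)
    individuals = [f"H{i:03d}" for i in range(n)]
    matrix = GenotypeMatrix(calls=calls, individuals=individuals,
                            snp_map=snp_map, sexes=sexes)
    return matrix, families


def simulate_gene_annotation(config: SimConfig, snp_map: pd.DataFrame,
                             rng=None) -> pd.DataFrame:
    """Gene annotation table with the configured tag-overlap structure.

    Genes are placed over runs of consecutive SNPs (so each gene
    contains genotyped markers) without overlapping each other; tag
    combinations follow ``config.intersections`` (the 5-gene triple
    intersection by default) with remaining counts filled by single-tag
    genes.  Raises if the requested intersections exceed a set size.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    combos: list[tuple[str, ...]] = []
    multi_by_tag = {t: 0 for t in config.set_sizes}
    for tags, count in config.intersections.items():
        for t in tags:
            multi_by_tag[t] = multi_by_tag.get(t, 0) + count
        combos += [tuple(tags)] * count
    for tag, size in config.set_sizes.items():
        remaining = size - multi_by_tag.get(tag, 0)
        if remaining < 0:
            raise ValueError(f"intersections for {tag} exceed its set size {size}")
        combos += [(tag,)] * remaining
    n_genes = len(combos)
    order = rng.permutation(n_genes)
    combos = [combos[i] for i in order]

    # non-overlapping gene spans over consecutive-SNP runs
    m = len(snp_map)
    span_lens = rng.integers(config.gene_min_span_snps,
                             config.gene_max_span_snps + 1, size=n_genes)
    needed = int(span_lens.sum()) + n_genes  # one-SNP gaps
    if needed > m:
        raise ValueError(f"{n_genes} genes need {needed} SNPs; map has {m}")
    gaps = rng.multinomial(m - needed, np.ones(n_genes + 1) / (n_genes + 1))
    pos = snp_map["position"].to_numpy()
    chrom = snp_map["chromosome"].to_numpy()
    rows = []
    cursor = 0
    for i in range(n_genes):
        cursor += gaps[i] + 1
        j0, j1 = cursor, cursor + span_lens[i] - 1
        # keep a gene on one chromosome: shift to the start of the next if split
        while chrom[j0] != chrom[min(j1, m - 1)]:
            cursor += 1
            j0, j1 = cursor, cursor + span_lens[i] - 1
        rows.append({
            "gene_id": f"G{i:04d}", "symbol": f"GENE{i:04d}",
            "chromosome": chrom[j0], "start": int(pos[j0]), "end": int(pos[j1]),
            "tags": ",".join(combos[i]),
        })
        cursor = j1
    return pd.DataFrame(rows)


def simulate_phenotype(matrix: GenotypeMatrix, genes: pd.DataFrame,
                       config: SimConfig, rng=None):
    """Quantitative phenotype from causal SNPs planted in tagged genes.

    Draws ``n_causal_per_set`` causal SNPs inside genes of each causal
    set (window 0), gives them equal effects, and adds Gaussian noise
    scaled so the genetic score explains ``h2`` of the variance.
    Returns (phenotype, genetic_score, truth table).
    """
    from .geneset import assign_snps_to_genes, build_gene_sets

    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    sets = build_gene_sets(genes, tags=tuple(config.set_sizes))
    gene2snps = assign_snps_to_genes(matrix.snp_map, genes, window=0)
    causal, causal_set = [], []
    for tag in config.causal_sets:
        pool = sorted({s for g in sets[tag] for s in gene2snps.get(g, [])} - set(causal))
        if len(pool) < config.n_causal_per_set:
            raise ValueError(f"set {tag} has only {len(pool)} assignable SNPs")
        chosen = list(rng.choice(pool, size=config.n_causal_per_set, replace=False))
        causal += chosen
        causal_set += [tag] * len(chosen)
    n = matrix.n_individuals
    if config.h2 == 0:
        if config.effect_size not in (None, 0, 0.0):
            raise ValueError("h2 = 0 with nonzero causal effects is inconsistent")
        effects = np.zeros(len(causal))
        y = rng.standard_normal(n)
        score = np.zeros(n)
    else:
        effects = np.full(len(causal), config.effect_size
                          if config.effect_size is not None else 1.0)
        cols = np.column_stack([np.nan_to_num(matrix.column(s)) for s in causal])
        score = cols @ effects
        var_g = float(np.var(score))
        var_e = var_g * (1 - config.h2) / config.h2
        y = score + rng.standard_normal(n) * np.sqrt(var_e)
    truth = pd.DataFrame({"snp_id": causal, "set": causal_set, "effect": effects})
    return y, score, truth


SEASON_STARTS = (date(2009, 3, 2), date(2010, 3, 1))  # Mondays, March of each season


def simulate_cytology_series(risk_score, config: SimConfig, rng=None,
                             sexes=None, individuals=None):
    """Weekly cytology + race records driven by the genetic risk score.

    Each horse is sampled weekly over its assigned season(s) (first /
    second / both).  A weekly bleeding event is Bernoulli with
    probability logistic(bleed_intercept + bleed_slope * standardized
    risk); haemosiderophage scores are 3 the week after an event, 2 the
    second week, 1 the third, then background 0/1.  Returns (cytology
    records DataFrame, race records DataFrame).
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    z = np.asarray(risk_score, dtype=float)
    sd = z.std()
    z = (z - z.mean()) / (sd if sd > 0 else 1.0)
    n = z.size
    individuals = individuals if individuals is not None else [f"H{i:03d}" for i in range(n)]
    sexes = sexes if sexes is not None else np.array([("M", "F")[i % 2] for i in range(n)], dtype=object)
    periods = rng.choice(["first", "second", "both"], size=n, p=(0.4, 0.35, 0.25))
    prob = 1.0 / (1.0 + np.exp(-(config.bleed_intercept + config.bleed_slope * z)))

    other_cats = [c for c in CATEGORIES if c != "haemosiderophages"]
    cyt_rows, race_rows = [], []
    for i in range(n):
        seasons = {"first": [0], "second": [1], "both": [0, 1]}[periods[i]]
        race_weeks_all = []
        for s in seasons:
            start = SEASON_STARTS[s]
            weeks_since_bleed = 99
            race_offset = int(rng.integers(0, 3))
            race_weeks = list(range(race_offset, config.n_weeks_per_season, 3))
            race_weeks_all.append((s, race_weeks))
            for w in range(config.n_weeks_per_season):
                d = start + timedelta(weeks=w)
                # haemosiderophages reflect bleeds at least one week old
                weeks_since_bleed += 1
                if weeks_since_bleed == 1:
                    hf = 3
                elif weeks_since_bleed == 2:
                    hf = 2
                elif weeks_since_bleed == 3:
                    hf = 1
                else:
                    hf = int(rng.random() < 0.1)
                if rng.random() < prob[i]:
                    weeks_since_bleed = 0
                row = {"horse_id": individuals[i], "date": d.isoformat(),
                       "haemosiderophages": hf,
                       "cell_density": int(rng.integers(0, 4))}
                for c in other_cats:
                    row[c] = int(rng.choice(4, p=(0.5, 0.3, 0.15, 0.05)))
                cyt_rows.append(row)
        dob = date(2005 + int(rng.integers(0, 3)), 1, 1) + timedelta(days=int(rng.integers(0, 300)))
        n_starts = 0
        first_start = last_start = None
        for s, race_weeks in race_weeks_all:
            for w in race_weeks:
                d = SEASON_STARTS[s] + timedelta(weeks=w, days=-2)
                n_starts += 1
                first_start = d if first_start is None else min(first_start, d)
                last_start = d if last_start is None else max(last_start, d)
        race_rows.append({
            "horse_id": individuals[i],
            "gender": "male" if str(sexes[i]).upper().startswith("M") else "female",
            "dob": dob.isoformat(),
            "n_starts": n_starts,
            "first_start": first_start.isoformat(),
            "last_start": last_start.isoformat(),
        })
    cols = ["horse_id", "date"] + CATEGORIES + ["cell_density"]
    cytology = pd.DataFrame(cyt_rows)[cols]
    races = pd.DataFrame(race_rows)
    return cytology, races


def simulate_cohort(config: SimConfig | None = None):
    """End-to-end synthetic cohort: all pipeline inputs plus the truth record.

    Returns a dict with keys matrix, families, genes, phenotype, score,
    truth, cytology, races.
    """
    config = config or SimConfig()
    matrix, families = simulate_genotypes(config)
    genes = simulate_gene_annotation(config, matrix.snp_map)
    y, score, truth = simulate_phenotype(matrix, genes, config)
    cytology, races = simulate_cytology_series(
        score if score.std() > 0 else y, config,
        sexes=matrix.sexes, individuals=matrix.individuals)
    return {
        "config": config, "matrix": matrix, "families": families,
        "genes": genes, "phenotype": y, "score": score, "truth": truth,
        "cytology": cytology, "races": races,
    }


def write_cohort(cohort: dict, outdir) -> dict:
    """Write every pipeline input format; returns the path manifest."""
    from pathlib import Path

    from .genio import write_ped_map

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "cohort.ped", "map": out / "cohort.map",
        "cytology": out / "cytology.tsv", "races": out / "races.tsv",
        "genes": out / "genes.tsv", "sets": out / "gene_sets.tsv",
        "truth": out / "truth.tsv",
    }
    write_ped_map(cohort["matrix"], paths["ped"], paths["map"])
    cohort["cytology"].to_csv(paths["cytology"], sep="\t", index=False)
    cohort["races"].to_csv(paths["races"], sep="\t", index=False)
    cohort["genes"].to_csv(paths["genes"], sep="\t", index=False)
    from .geneset import build_gene_sets
    sets = build_gene_sets(cohort["genes"], tags=tuple(cohort["config"].set_sizes))
    pd.DataFrame(
        [(name, sym) for name, members in sets.items() for sym in members],
        columns=["set_name", "symbol"],
    ).to_csv(paths["sets"], sep="\t", index=False)
    cohort["truth"].to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
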