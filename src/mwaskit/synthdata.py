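"""Synthetic metagenomic cohorts with planted ground truth.

Real gut-metagenome gene profiles arise from mapping reads against a large
reference gene catalog; each microbial genome contributes a block of genes
whose abundances co-vary across samples because they travel on the same
chromosome.  This module emulates that structure at toy scale so that every
downstream stage (binning, differential testing, reporter scores, marker
selection) can be tested against a known answer:

* a catalog of genomes, each owning a block of genes, with partial KO /
  enzyme-family / virus annotations and a KEGG-style module map;
* a community model — log-normal genome abundances across samples, fixed
  per-gene weights (so genes of one genome stay proportional), multinomial
  count noise at a configured sequencing depth, optional zero inflation,
  case/control fold changes on selected genomes, drug effects, and clinical
  indices responding linearly to selected genomes;
* the ground truth needed for parameter-recovery assertions.

All randomness flows through one :class:`numpy.random.Generator` derived from
an explicit integer seed; the same seed yields bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCatalog",
    "CommunityModel",
    "GroundTruth",
    "AnnotationRates",
    "generate_catalog",
    "simulate_cohort",
    "write_cohort",
]

#: Trimethylamine-lyase families quantified in the ACVD analysis: the choline
#: lyase CutC with its activator CutD, and the promiscuous YeaW/YeaX pair.
TMA_LYASE_FAMILIES = ("CutC", "CutD", "YeaW", "YeaX")


@dataclass(frozen=True)
class AnnotationRates:
    """Fractions of catalog genes receiving each annotation type."""

    ko: float = 0.4
    enzyme: float = 0.01
    virus: float = 0.05

    def __post_init__(self) -> None:
        for name in ("ko", "enzyme", "virus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"annotation rate {name}={v} outside [0, 1]")


@dataclass
class SyntheticCatalog:
    """A toy reference gene catalog with genome-block structure."""

    genome_ids: list[str]
    genes_per_genome: dict[str, int]
    gene_to_genome: dict[str, str]
    gene_to_ko: dict[str, str]
    gene_to_enzyme: dict[str, str]
    gene_to_virus: dict[str, str]
    module_map: dict[str, set[str]]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gene_to_genome)

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_genome)

    def genes_of(self, genome_id: str) -> list[str]:
        return [g for g, gn in self.gene_to_genome.items() if gn == genome_id]

    def validate(self) -> None:
        if set(self.gene_to_genome.values()) - set(self.genome_ids):
            raise ValueError("gene assigned to genome absent from genome_ids")
        sizes = pd.Series(list(self.gene_to_genome.values())).value_counts()
        for gid, n in self.genes_per_genome.items():
            if n < 1:
                raise ValueError(f"genome {gid} has {n} genes; need >= 1")
            if sizes.get(gid, 0) != n:
                raise ValueError(f"genome {gid}: declared {n} genes, found {sizes.get(gid, 0)}")
        kos = set(self.gene_to_ko.values())
        for mod, members in self.module_map.items():
            if not members:
                raise ValueError(f"module {mod} is empty")
            if members - kos:
                raise ValueError(f"module {mod} references unassigned KOs")


@dataclass
class CommunityModel:
    """Generative parameters for a case/control cohort.

    ``baseline_log_abundance`` is the per-genome location of a log-normal
    community profile (natural log); ``dispersion`` the per-sample log-scale
    sd around it.  ``case_log2_fold_change`` shifts selected genomes in case
    samples.  ``clinical_effect_map`` ties a clinical index to one genome via
    ``index -> (genome, slope, noise_sd)``; ``drug_effect_map`` shifts a
    genome in drug-treated case samples via ``drug -> (genome, log2_fc)``.
    """

    baseline_log_abundance: dict[str, float]
    dispersion: float = 1.0
    case_log2_fold_change: dict[str, float] = field(default_factory=dict)
    sequencing_depth: int = 100_000
    zero_inflation: float = 0.0
    gene_weight_sd: float = 1.0
    clinical_effect_map: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    drug_effect_map: dict[str, tuple[str, float]] = field(default_factory=dict)
    n_null_indices: int = 3

    def validate(self, catalog: SyntheticCatalog) -> None:
        known = set(catalog.genome_ids)
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        for gid, fc in self.case_log2_fold_change.items():
            if gid not in known:
                raise ValueError(f"fold change on unknown genome {gid!r}")
            if not np.isfinite(fc):
                raise ValueError(f"non-finite fold change for genome {gid!r}")
        for drug, (gid, _) in self.drug_effect_map.items():
            if gid not in known:
                raise ValueError(f"drug {drug!r} targets unknown genome {gid!r}")
        for idx, (gid, _, sd) in self.clinical_effect_map.items():
            if gid not in known:
                raise ValueError(f"clinical index {idx!r} tied to unknown genome {gid!r}")
            if sd < 0:
                raise ValueError(f"clinical index {idx!r} has negative noise sd")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    true_bins: dict[str, str]
    true_enriched: set[str]
    true_depleted: set[str]
    true_module_direction: dict[str, int]
    true_clinical_pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.true_enriched & self.true_depleted:
            raise ValueError("enriched and depleted genome sets overlap")

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_bins": self.true_bins,
                "true_enriched": sorted(self.true_enriched),
                "true_depleted": sorted(self.true_depleted),
                "true_module_direction": self.true_module_direction,
                "true_clinical_pairs": sorted(map(list, self.true_clinical_pairs)),
            },
            indent=1,
        )


def generate_catalog(
    n_genomes: int,
    genes_per_genome_range: tuple[int, int] = (100, 300),
    annotation_rates: AnnotationRates | None = None,
    seed: int = 0,
    n_modules: int = 20,
    kos_per_module_range: tuple[int, int] = (3, 8),
    n_ko_universe: int | None = None,
) -> SyntheticCatalog:
    """Draw a toy gene catalog: genomes, gene blocks, annotation maps.

    Gene ids are ``g<genome index>_<gene index>`` so the planted partition is
    readable; genome ids are ``genome<k>``.  KO labels are recycled across
    genomes (many genes -> one KO), mirroring orthology.  A small fraction of
    genes get enzyme-family labels drawn from the TMA-lyase families, and a
    fraction get virus labels.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    lo, hi = genes_per_genome_range
    if lo < 1 or hi < lo:
        raise ValueError("genes_per_genome_range must satisfy 1 <= lo <= hi")
    rates = annotation_rates or AnnotationRates()
    rng = np.random.default_rng(seed)

    genome_ids = [f"genome{k:03d}" for k in range(n_genomes)]
    sizes = rng.integers(lo, hi + 1, size=n_genomes)
    genes_per_genome = {gid: int(n) for gid, n in zip(genome_ids, sizes)}

    gene_to_genome: dict[str, str] = {}
    for k, gid in enumerate(genome_ids):
        for j in range(genes_per_genome[gid]):
            gene_to_genome[f"g{k:03d}_{j:04d}"] = gid
    genes = list(gene_to_genome)
    n_genes = len(genes)

    n_kos = n_ko_universe or max(20, n_genes // 20)
    ko_labels = [f"K{k:05d}" for k in range(n_kos)]

    gene_to_ko: dict[str, str] = {}
    if rates.ko > 0:
        picked = rng.random(n_genes) < rates.ko
        assignments = rng.integers(0, n_kos, size=n_genes)
        gene_to_ko = {g: ko_labels[a] for g, a, p in zip(genes, assignments, picked) if p}

    gene_to_enzyme: dict[str, str] = {}
    if rates.enzyme > 0:
        picked = rng.random(n_genes) < rates.enzyme
        fams = rng.integers(0, len(TMA_LYASE_FAMILIES), size=n_genes)
        gene_to_enzyme = {
            g: TMA_LYASE_FAMILIES[f] for g, f, p in zip(genes, fams, picked) if p
        }

    gene_to_virus: dict[str, str] = {}
    if rates.virus > 0:
        n_viruses = max(3, n_genomes // 5)
        picked = rng.random(n_genes) < rates.virus
        vs = rng.integers(0, n_viruses, size=n_genes)
        gene_to_virus = {g: f"virus{v:03d}" for g, v, p in zip(genes, vs, picked) if p}

    # modules draw only from KOs actually assigned to catalog genes
    module_map: dict[str, set[str]] = {}
    assigned_kos = sorted(set(gene_to_ko.values()))
    if assigned_kos:
        for m in range(n_modules):
            k = int(rng.integers(kos_per_module_range[0], kos_per_module_range[1] + 1))
            k = min(k, len(assigned_kos))
            members = rng.choice(len(assigned_kos), size=k, replace=False)
            module_map[f"M{m:05d}"] = {assigned_kos[i] for i in members}

    cat = SyntheticCatalog(
        genome_ids=genome_ids,
        genes_per_genome=genes_per_genome,
        gene_to_genome=gene_to_genome,
        gene_to_ko=gene_to_ko,
        gene_to_enzyme=gene_to_enzyme,
        gene_to_virus=gene_to_virus,
        module_map=module_map,
    )
    cat.validate()
    return cat


def _module_directions(
    catalog: SyntheticCatalog, lfcs: Mapping[str, float]
) -> dict[str, int]:
    """Net planted direction per module: sign of the summed fold change of
    the genomes carrying its KOs (0 when no planted genome contributes)."""
    ko_shift: dict[str, float] = {}
    for gene, ko in catalog.gene_to_ko.items():
        fc = lfcs.get(catalog.gene_to_genome[gene], 0.0)
        ko_shift[ko] = ko_shift.get(ko, 0.0) + fc
    out: dict[str, int] = {}
    for mod, kos in catalog.module_map.items():
        s = sum(ko_shift.get(k, 0.0) for k in kos)
        out[mod] = int(np.sign(s))
    return out


def simulate_cohort(
    catalog: SyntheticCatalog,
    model: CommunityModel,
    n_case: int,
    n_control: int,
    seed: int = 0,
    case_drug_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a case/control cohort from a catalog and community model.

    Returns ``(counts, metadata, truth)``: a gene-by-sample integer count
    matrix, a per-sample metadata table (group, subtype, drug flags, clinical
    indices), and the planted :class:`GroundTruth`.

    Genes of one genome share the genome's latent per-sample abundance and a
    fixed log-normal per-gene weight, so within-genome profiles are
    proportional up to multinomial count noise — exactly the co-abundance
    signal MLG binning exploits.  Case samples multiply planted genomes by
    ``2**case_log2_fold_change``; drug-treated case samples additionally
    apply drug effects.  Clinical indices are linear in the log relative
    abundance of their target genome plus Gaussian noise.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one case and one control sample")
    model.validate(catalog)
    rng = np.random.default_rng(seed)

    genes = catalog.gene_ids
    genomes = catalog.genome_ids
    n_samples = n_case + n_control
    sample_ids = [f"case{j:04d}" for j in range(n_case)] + [
        f"ctrl{j:04d}" for j in range(n_control)
    ]
    is_case = np.array([1] * n_case + [0] * n_control, dtype=bool)

    # fixed per-gene weight: keeps genes of one genome proportional
    gene_weight = np.exp(rng.normal(0.0, model.gene_weight_sd, size=len(genes)))
    genome_index = pd.Index(genomes)
    gene_genome_pos = genome_index.get_indexer([catalog.gene_to_genome[g] for g in genes])

    base = np.array([model.baseline_log_abundance.get(g, 0.0) for g in genomes])
    lfc = np.array([model.case_log2_fold_change.get(g, 0.0) for g in genomes])

    # drug assignment: only case samples can be treated
    drug_flags = {}
    for drug in model.drug_effect_map:
        flags = np.zeros(n_samples, dtype=bool)
        flags[:n_case] = rng.random(n_case) < case_drug_fraction
        drug_flags[drug] = flags

    # latent genome abundance per sample (log-normal, case shifts, drug shifts)
    log_ab = base[:, None] + rng.normal(0.0, model.dispersion, size=(len(genomes), n_samples))
    log_ab[:, is_case] += (lfc[:, None] * np.log(2.0))[:, :]
    for drug, (gid, dfc) in model.drug_effect_map.items():
        gi = genome_index.get_loc(gid)
        log_ab[gi, drug_flags[drug]] += dfc * np.log(2.0)
    genome_ab = np.exp(log_ab)

    # per-gene expected share, multinomial counts per sample
    gene_intensity = genome_ab[gene_genome_pos, :] * gene_weight[:, None]
    probs = gene_intensity / gene_intensity.sum(axis=0, keepdims=True)
    counts = np.empty((len(genes), n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(model.sequencing_depth, probs[:, s])
    if model.zero_inflation > 0:
        dropout = rng.random(counts.shape) < model.zero_inflation
        counts[dropout] = 0

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_ids)

    # clinical indices respond to log relative genome abundance
    rel_genome = genome_ab / genome_ab.sum(axis=0, keepdims=True)
    clinical: dict[str, np.ndarray] = {}
    for idx, (gid, slope, noise_sd) in model.clinical_effect_map.items():
        gi = genome_index.get_loc(gid)
        x = np.log(rel_genome[gi, :])
        x = (x - x.mean()) / (x.std() or 1.0)
        clinical[idx] = slope * x + rng.normal(0.0, noise_sd, size=n_samples)
    for j in range(model.n_null_indices):
        clinical[f"null_index{j}"] = rng.normal(0.0, 1.0, size=n_samples)

    subtype = np.where(is_case, "stable_angina", "none")
    meta = pd.DataFrame({"group": np.where(is_case, "case", "control"), "subtype": subtype},
                        index=pd.Index(sample_ids, name="sample"))
    for drug, flags in drug_flags.items():
        meta[f"drug_{drug}"] = flags.astype(int)
    for idx, vals in clinical.items():
        meta[idx] = vals

    truth = GroundTruth(
        true_bins=dict(catalog.gene_to_genome),
        true_enriched={g for g, f in model.case_log2_fold_change.items() if f > 0},
        true_depleted={g for g, f in model.case_log2_fold_change.items() if f < 0},
        true_module_direction=_module_directions(catalog, model.case_log2_fold_change),
        true_clinical_pairs={(g, i) for i, (g, s, _) in model.clinical_effect_map.items() if s != 0},
    )
    return counts_df, meta, truth


def default_community_model(
    catalog: SyntheticCatalog,
    n_enriched: int = 5,
    n_depleted: int = 5,
    log2_fold_change: float = 2.0,
    seed: int = 0,
    n_clinical: int = 2,
    n_drugs: int = 2,
    drug_log2_fc: float = 1.5,
) -> CommunityModel:
    """A reasonable default model: heavy-tailed baseline, a handful of
    planted case-enriched / depleted genomes, two drug effects, two clinical
    indices tied to planted genomes."""
    rng = np.random.default_rng(seed)
    baselines = {g: float(rng.normal(0.0, 1.5)) for g in catalog.genome_ids}
    order = [str(g) for g in rng.permutation(catalog.genome_ids)]
    enriched = order[:n_enriched]
    depleted = order[n_enriched : n_enriched + n_depleted]
    lfc = {g: log2_fold_change for g in enriched}
    lfc.update({g: -log2_fold_change for g in depleted})
    clinical = {}
    for j in range(min(n_clinical, len(enriched))):
        clinical[f"index{j}"] = (enriched[j], 1.0, 0.5)
    drugs = {}
    rest = order[n_enriched + n_depleted :]
    for j in range(min(n_drugs, len(rest))):
        drugs[f"drug{j}"] = (rest[j], drug_log2_fc)
    return CommunityModel(
        baseline_log_abundance=baselines,
        dispersion=1.0,
        case_log2_fold_change=lfc,
        clinical_effect_map=clinical,
        drug_effect_map=drugs,
    )


def write_cohort(
    outdir: str | Path,
    catalog: SyntheticCatalog,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the cohort as plain TSV/JSON files; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "gene_to_genome": outdir / "gene_to_genome.tsv",
        "gene_to_ko": outdir / "gene_to_ko.tsv",
        "gene_to_enzyme": outdir / "gene_to_enzyme.tsv",
        "gene_to_virus": outdir / "gene_to_virus.tsv",
        "module_map": outdir / "module_map.tsv",
        "truth": outdir / "truth.json",
    }
    counts.to_csv(paths["counts"], sep="\t")
    metadata.to_csv(paths["metadata"], sep="\t")
    for key, mapping in [
        ("gene_to_genome", catalog.gene_to_genome),
        ("gene_to_ko", catalog.gene_to_ko),
        ("gene_to_enzyme", catalog.gene_to_enzyme),
        ("gene_to_virus", catalog.gene_to_virus),
    ]:
        pd.Series(mapping, name="feature").rename_axis("gene").to_csv(paths[key], sep="\t")
    rows = [(m, k) for m, kos in catalog.module_map.items() for k in sorted(kos)]
    pd.DataFrame(rows, columns=["module", "ko"]).to_csv(paths["module_map"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    return paths
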