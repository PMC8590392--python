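"""Synthetic cohorts with the statistical structure the pipeline assumes.

Populations diverge from a shared ancestral allele frequency under the
Balding-Nichols model: at differentiation level F > 0, a subpopulation's
frequency is Beta(p*(1-F)/F, (1-p)*(1-F)/F)-distributed around the ancestral
frequency p, giving variance F*p*(1-p) — so F is exactly the quantity the
Weir-Cockerham estimator targets, which closes the loop for
parameter-recovery testing.  Genotypes are drawn from Hardy-Weinberg
proportions; optional uniform missingness is applied per call.

Planted loci override the Balding-Nichols draw with per-population target
frequencies and carry truth labels (shared-significant, unique-A, unique-B,
high-fst), so classification can be validated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    Annotation,
    AnnotationTable,
    ReferenceFrequencySet,
    SamplePanel,
    VariantRecord,
)

PLANTED_CATEGORIES = ("shared-significant", "unique-A", "unique-B", "high-fst")

#: consequence classes cycled over background loci
_BACKGROUND_CONSEQUENCES = ("intronic", "synonymous", "missense", "3'UTR", "5'UTR")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_subpopulation_frequencies(
    p_ancestral: float,
    F: float,
    n_pops: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies around an ancestral frequency.

    With F = 0 every population receives exactly ``p_ancestral``; with F > 0
    each frequency is an independent Beta draw with mean p and variance
    F*p*(1-p).
    """
    if not 0.0 < p_ancestral < 1.0:
        if F > 0.0:
            raise ValueError(
                f"ancestral frequency {p_ancestral} is degenerate for F={F} > 0"
            )
        return np.full(n_pops, p_ancestral)
    if not 0.0 <= F < 1.0:
        raise ValueError(f"F must be in [0, 1), got {F}")
    if F == 0.0:
        return np.full(n_pops, p_ancestral)
    rng = _rng(seed)
    shape = (1.0 - F) / F
    return rng.beta(p_ancestral * shape, (1.0 - p_ancestral) * shape, size=n_pops)


def sample_genotypes(
    freq: float,
    n: int,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Diploid dosages for *n* samples under Hardy-Weinberg proportions.

    Dosage ~ Binomial(2, freq) per sample; each entry is independently
    replaced by the missing sentinel with probability *missing_rate*.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {freq}")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {missing_rate}")
    rng = _rng(seed)
    dosage = rng.binomial(2, freq, size=n).astype(np.int8)
    if missing_rate > 0.0:
        dosage[rng.random(n) < missing_rate] = MISSING
    return dosage


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: label, diploid size, divergence F, role."""

    label: str
    n: int
    F: float = 0.0
    role: str = "focal"  # "focal" or "reference"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"population {self.label}: sample size must be >= 1")
        if not 0.0 <= self.F < 1.0:
            raise ValueError(f"population {self.label}: F must be in [0, 1)")
        if self.role not in ("focal", "reference"):
            raise ValueError(f"population {self.label}: role must be focal/reference")


@dataclass(frozen=True)
class PlantedLocus:
    """A locus with prescribed per-population frequencies and a truth label.

    ``frequencies`` maps population label -> target frequency; the special
    key ``"*"`` supplies the default for unlisted populations.
    """

    category: str
    frequencies: dict[str, float]
    gene: str
    consequence: str = "intronic"
    cadd: float | None = None

    def __post_init__(self) -> None:
        if self.category not in PLANTED_CATEGORIES:
            raise ValueError(f"unknown planted category: {self.category}")
        for pop, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"planted frequency {f} for {pop} outside [0, 1]")

    def target(self, label: str) -> float | None:
        if label in self.frequencies:
            return self.frequencies[label]
        return self.frequencies.get("*")


@dataclass(frozen=True)
class SimulationConfig:
    n_loci: int
    populations: tuple[PopulationSpec, ...]
    ancestral: tuple[float, float] = (0.05, 0.95)  # uniform range; (v, v) pins p
    missing_rate: float = 0.0
    planted: tuple[PlantedLocus, ...] = ()
    genes: tuple[str, ...] = ("GENE1", "GENE2", "GENE3", "GENE4", "GENE5")
    pharmgkb_fraction: float = 1.0
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if len(self.planted) > self.n_loci:
            raise ValueError(
                f"{len(self.planted)} planted loci exceed n_loci={self.n_loci}"
            )
        lo, hi = self.ancestral
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"ancestral frequency range {self.ancestral} outside (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")

    @property
    def focal_populations(self) -> list[str]:
        return [p.label for p in self.populations if p.role == "focal"]

    @property
    def reference_populations(self) -> list[str]:
        return [p.label for p in self.populations if p.role == "reference"]


@dataclass
class SimulatedCohort:
    """A simulated study: genotypes, panel, reference table, annotations, truth."""

    variants: list[VariantRecord]
    panel: SamplePanel
    references: ReferenceFrequencySet
    annotations: AnnotationTable
    truth: pd.DataFrame  # columns: variant, category, gene, high_fst_target
    true_frequencies: pd.DataFrame  # columns: variant, population, frequency
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Deterministically generate a cohort from *config* (pure in the seed)."""
    rng = np.random.default_rng(config.seed)
    pops = config.populations
    labels = [p.label for p in pops]

    # where the planted loci sit among the n_loci sites
    planted_idx = (
        np.sort(rng.choice(config.n_loci, size=len(config.planted), replace=False))
        if config.planted
        else np.empty(0, dtype=int)
    )
    planted_at = {int(i): config.planted[j] for j, i in enumerate(planted_idx)}

    lo, hi = config.ancestral
    panel = SamplePanel([
        (f"{p.label}_{i:04d}", p.label, None) for p in pops for i in range(p.n)
    ])
    pop_slices: list[tuple[PopulationSpec, slice]] = []
    start = 0
    for p in pops:
        pop_slices.append((p, slice(start, start + p.n)))
        start += p.n

    variants: list[VariantRecord] = []
    truth_rows = []
    freq_rows = []
    references = ReferenceFrequencySet()
    annotations = AnnotationTable()
    gene_cycle = 0
    bases = ("A", "C", "G", "T")

    for i in range(config.n_loci):
        rsid = f"rs{1_000_000 + i}"
        pos = 10_000 + 100 * i
        p_anc = lo if lo == hi else float(rng.uniform(lo, hi))
        planted = planted_at.get(i)
        freqs = {}
        for spec in pops:
            target = planted.target(spec.label) if planted is not None else None
            if target is not None:
                freqs[spec.label] = float(target)
            else:
                freqs[spec.label] = float(
                    draw_subpopulation_frequencies(p_anc, spec.F, 1, rng)[0]
                )
        dosage = np.empty(len(panel), dtype=np.int8)
        for spec, sl in pop_slices:
            dosage[sl] = sample_genotypes(
                freqs[spec.label], spec.n, config.missing_rate, rng
            )
        ref_base = bases[i % 4]
        alt_base = bases[(i + 1) % 4]
        rec = VariantRecord(
            chrom=config.chrom, pos=pos, rsid=rsid, ref=ref_base, alt=alt_base,
            genotypes=dosage,
        )
        variants.append(rec)

        for spec, sl in pop_slices:
            freq_rows.append((rsid, spec.label, freqs[spec.label]))
            if spec.role == "reference":
                g = dosage[sl]
                called = g != MISSING
                an = 2 * int(called.sum())
                realized = float(g[called].sum() / an) if an else 0.0
                references.add(
                    rsid, spec.label, realized, max(an, 1), alias=rec.coordinate_key
                )

        if planted is not None:
            gene = planted.gene
            consequence = planted.consequence
            cadd = planted.cadd if planted.cadd is not None else float(rng.uniform(0, 30))
            truth_rows.append(
                (rsid, planted.category, gene, planted.category == "high-fst")
            )
        else:
            gene = config.genes[gene_cycle % len(config.genes)]
            gene_cycle += 1
            consequence = _BACKGROUND_CONSEQUENCES[i % len(_BACKGROUND_CONSEQUENCES)]
            cadd = float(rng.uniform(0, 30))
        pharmgkb = (
            True
            if config.pharmgkb_fraction >= 1.0
            else bool(rng.random() < config.pharmgkb_fraction)
        )
        annotations.add(rsid, Annotation(gene, consequence, round(cadd, 3), pharmgkb))

    truth = pd.DataFrame(
        truth_rows, columns=["variant", "category", "gene", "high_fst_target"]
    )
    true_frequencies = pd.DataFrame(
        freq_rows, columns=["variant", "population", "frequency"]
    )
    return SimulatedCohort(
        variants=variants,
        panel=panel,
        references=references,
        annotations=annotations,
        truth=truth,
        true_frequencies=true_frequencies,
        config=config,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Emit VCF + panel + reference-frequency + annotation + truth files."""
    import os

    from .io import (
        write_annotations,
        write_panel,
        write_reference_frequencies,
        write_vcf,
    )

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "panel": os.path.join(outdir, "panel.tsv"),
        "references": os.path.join(outdir, "reference_frequencies.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_vcf(cohort.variants, cohort.panel, paths["vcf"])
    write_panel(cohort.panel, paths["panel"])
    write_reference_frequencies(cohort.references, paths["references"])
    write_annotations(cohort.annotations, paths["annotations"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Ready-made study configurations
# ---------------------------------------------------------------------------

#: focal cohort sizes: 109 and 112 diploid genomes, the sizes of the two
#: South-Asian 1000 Genomes cohorts this design emulates
FOCAL_A, FOCAL_B = "GIH", "ITU"
DEFAULT_FOCAL_SIZES = {FOCAL_A: 109, FOCAL_B: 112}

#: six reference populations with 1000-Genomes-like panel sizes
DEFAULT_REFERENCE_SIZES = {
    "AFR": 661,
    "EAS": 504,
    "EUR": 503,
    "SAS": 489,
    "AMR1": 170,
    "AMR2": 177,
}

# gene lists reproducing the gene multiplicities of the three headline
# categories: 13 shared SNPs in 10 genes, 9 unique-A SNPs in 8 genes,
# 6 unique-B SNPs in 6 genes
SHARED_GENES = (
    "CYP2C9", "DPYD", "ABCB1", "VKORC1", "VKORC1", "VKORC1", "CYP2B6",
    "TYMS", "CYP1A2", "CYP3A4", "DPYD", "NR1I2", "COMT",
)
UNIQUE_A_GENES = (
    "NQO1", "GSTP1", "DPYD", "DRD2", "ABCG2", "VKORC1", "VKORC1",
    "CYP2A13", "SLCO1B1",
)
UNIQUE_B_GENES = ("NUDT15", "EGFR", "ABCG2", "F5", "VKORC1", "VDR")

BACKGROUND_GENES = (
    "ALK", "CFTR", "KCNJ11", "KRAS", "BCR", "VDR", "EGFR", "SLC19A1",
    "TPMT", "UGT1A1", "G6PD", "ACE", "ADRB2", "AHR", "CYP2D6", "CYP3A5",
)

#: target frequencies for planted contrasts: the elevated side sits at 0.65
#: against references at 0.20 (contrast 0.45 >= 0.4); high-Fst-targeted loci
#: use 0.85 vs 0.10 so per-site theta clears the 0.5 screen with margin
PLANT_HIGH, PLANT_BASE = 0.65, 0.20
PLANT_FST_HIGH, PLANT_FST_BASE = 0.85, 0.10


def default_populations(
    focal_F: float = 0.0, reference_F: float = 0.0
) -> tuple[PopulationSpec, ...]:
    focal = [
        PopulationSpec(label, n, focal_F, "focal")
        for label, n in DEFAULT_FOCAL_SIZES.items()
    ]
    refs = [
        PopulationSpec(label, n, reference_F, "reference")
        for label, n in DEFAULT_REFERENCE_SIZES.items()
    ]
    return tuple(focal + refs)


def classification_demo_config(seed: int = 0, n_loci: int = 250) -> SimulationConfig:
    """The packaged demo cohort: 13 shared / 9 unique-A / 6 unique-B planted
    loci with the headline gene multiplicities, among undifferentiated
    background loci, at the emulated cohort sizes (109/112 diploids vs six
    reference panels).

    The three shared loci in VKORC1 are planted at the stronger 0.85-vs-0.10
    contrast so they also clear the per-site Fst >= 0.5 screen in both focal
    populations.
    """
    planted: list[PlantedLocus] = []
    for gene in SHARED_GENES:
        if gene == "VKORC1":
            freqs = {FOCAL_A: PLANT_FST_HIGH, FOCAL_B: PLANT_FST_HIGH, "*": PLANT_FST_BASE}
        else:
            freqs = {FOCAL_A: PLANT_HIGH, FOCAL_B: PLANT_HIGH, "*": PLANT_BASE}
        planted.append(PlantedLocus("shared-significant", freqs, gene))
    for gene in UNIQUE_A_GENES:
        planted.append(
            PlantedLocus(
                "unique-A",
                {FOCAL_A: PLANT_HIGH, FOCAL_B: PLANT_BASE, "*": PLANT_BASE},
                gene,
            )
        )
    for gene in UNIQUE_B_GENES:
        planted.append(
            PlantedLocus(
                "unique-B",
                {FOCAL_A: PLANT_BASE, FOCAL_B: PLANT_HIGH, "*": PLANT_BASE},
                gene,
            )
        )
    return SimulationConfig(
        n_loci=n_loci,
        populations=default_populations(),
        planted=tuple(planted),
        genes=BACKGROUND_GENES,
        seed=seed,
    )


def null_config(
    seed: int = 0, n_loci: int = 250, n_focal: int = 100
) -> SimulationConfig:
    """A fully undifferentiated cohort (F = 0 everywhere, nothing planted):
    every significance call downstream is a false positive."""
    focal = [
        PopulationSpec(FOCAL_A, n_focal, 0.0, "focal"),
        PopulationSpec(FOCAL_B, n_focal, 0.0, "focal"),
    ]
    refs = [
        PopulationSpec(label, n, 0.0, "reference")
        for label, n in DEFAULT_REFERENCE_SIZES.items()
    ]
    return SimulationConfig(
        n_loci=n_loci,
        populations=tuple(focal + refs),
        genes=BACKGROUND_GENES,
        seed=seed,
    )


def two_population_config(
    F: float,
    n_loci: int = 500,
    n_per_pop: int = 50,
    seed: int = 0,
) -> SimulationConfig:
    """Two populations diverged at level F — the setting for PCA separation
    and Fst parameter-recovery checks."""
    pops = (
        PopulationSpec("POP1", n_per_pop, F, "focal"),
        PopulationSpec("POP2", n_per_pop, F, "focal"),
    )
    return SimulationConfig(n_loci=n_loci, populations=pops, seed=seed)
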