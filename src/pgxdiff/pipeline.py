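"""End-to-end orchestration: stages, artifacts and the run manifest.

The stages mirror the analysis flow: (simulate) -> frequencies -> MAF filter
-> harmonize with references -> two-way chi-square + Bonferroni -> Fst screen
-> classification/PCA -> reports.  A single :class:`RunConfig` carries every
threshold so the Bonferroni denominator is always computed from the actual
filtered variant count, never hand-entered.  All artifacts are TSV/JSON and
byte-reproducible from the config and seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import io as pio
from .classify import (
    apply_high_fst,
    classify_shared_unique,
    summarize_by_gene,
)
from .differentiation import BonferroniScheme, call_significance, chi_square_table
from .frequencies import (
    DEFAULT_EPSILON,
    compute_population_frequencies,
    filter_by_maf,
    harmonize_with_reference,
)
from .fst import flag_high_fst, wc_theta_from_genotypes
from .pca import genotype_pca
from .types import SamplePanel, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and options for one pipeline run."""

    vcf: str | None = None
    panel: str | None = None
    references: str | None = None
    annotations: str | None = None
    out_dir: str = "pgxdiff_out"
    focal_populations: tuple[str, str] = ("GIH", "ITU")
    maf_threshold: float = 0.05
    alpha: float = 0.05
    cadd_threshold: float = 15.0
    fst_threshold: float = 0.5
    epsilon: float = DEFAULT_EPSILON
    scale: str = "counts"
    expected: str = "pooled"
    df: int = 1
    pca_components: int = 2
    seed: int = 0
    simulate: dict | None = None  # forwarded to the synthetic generator

    def validate(self) -> None:
        problems = []
        if not 0.0 <= self.maf_threshold <= 0.5:
            problems.append(f"maf_threshold {self.maf_threshold} outside [0, 0.5]")
        if not 0.0 < self.alpha <= 1.0:
            problems.append(f"alpha {self.alpha} outside (0, 1]")
        if not 0.0 <= self.fst_threshold <= 1.0:
            problems.append(f"fst_threshold {self.fst_threshold} outside [0, 1]")
        if self.cadd_threshold < 0:
            problems.append(f"cadd_threshold {self.cadd_threshold} negative")
        if not 0.0 < self.epsilon < 0.5:
            problems.append(f"epsilon {self.epsilon} outside (0, 0.5)")
        if self.scale not in ("counts", "frequencies"):
            problems.append(f"scale {self.scale!r} not counts/frequencies")
        if self.expected not in ("pooled", "per-side"):
            problems.append(f"expected {self.expected!r} not pooled/per-side")
        if self.df < 1:
            problems.append(f"df {self.df} < 1")
        if len(self.focal_populations) != 2:
            problems.append("exactly two focal populations are required")
        if self.simulate is None:
            for name in ("vcf", "panel", "references", "annotations"):
                path = getattr(self, name)
                if path is None:
                    problems.append(f"{name}: no path given and simulation disabled")
                elif not os.path.exists(path):
                    problems.append(f"{name}: file not found: {path}")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        if "focal_populations" in raw:
            raw["focal_populations"] = tuple(raw["focal_populations"])
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory results of a full pipeline run."""

    variants: list[VariantRecord]
    panel: SamplePanel
    frequencies: pd.DataFrame
    retained: list[str]
    low_maf: list[str]
    calls: dict[str, pd.DataFrame]  # focal population -> called statistic table
    low_maf_calls: dict[str, pd.DataFrame]
    fst: pd.DataFrame
    high_fst: set[str]
    classifications: pd.DataFrame
    gene_summary: pd.DataFrame
    pca: pd.DataFrame | None
    manifest: dict


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        from .simulate import SimulationConfig, simulate_cohort

        sim_conf = config.simulate
        if isinstance(sim_conf, SimulationConfig):
            cohort = simulate_cohort(sim_conf)
        else:
            cohort = simulate_cohort(SimulationConfig(**sim_conf))
        return cohort.variants, cohort.panel, cohort.references, cohort.annotations
    panel = pio.read_panel(config.panel)
    scan = pio.read_vcf(config.vcf, panel)
    refs = pio.read_reference_frequencies(config.references)
    annotations = pio.read_annotations(config.annotations)
    return scan.records, panel, refs, annotations


def run_all(config: RunConfig, write_artifacts: bool = True) -> RunResult:
    """Run every stage and (optionally) write the TSV artifacts + manifest."""
    config.validate()
    focal_a, focal_b = config.focal_populations
    variants, panel, references, annotations = _load_inputs(config)
    counts: dict[str, int] = {"variants_in": len(variants)}

    freqs = compute_population_frequencies(variants, panel)
    partition = filter_by_maf(freqs, config.maf_threshold, list(config.focal_populations))
    counts["maf_retained"] = len(partition.retained)
    counts["maf_low"] = len(partition.low_maf)

    ref_pops = references.populations
    scheme = BonferroniScheme(
        alpha=config.alpha,
        n_variants=max(len(partition.retained), 1),
        n_reference_pops=max(len(ref_pops), 1),
    )
    low_scheme = BonferroniScheme(
        alpha=config.alpha,
        n_variants=max(len(partition.low_maf), 1),
        n_reference_pops=max(len(ref_pops), 1),
    )

    calls: dict[str, pd.DataFrame] = {}
    low_calls: dict[str, pd.DataFrame] = {}
    for focal in config.focal_populations:
        for variant_set, scheme_used, sink in (
            (partition.retained, scheme, calls),
            (partition.low_maf, low_scheme, low_calls),
        ):
            pairs = harmonize_with_reference(
                freqs,
                references,
                [focal],
                ref_pops,
                epsilon=config.epsilon,
                variants=variant_set,
            )
            stats = chi_square_table(
                pairs, scale=config.scale, expected=config.expected, df=config.df
            )
            sink[focal] = call_significance(stats, scheme_used)
        counts[f"significant_{focal}"] = int(
            calls[focal]["significant"].sum()
        ) if len(calls[focal]) else 0

    # Fst needs genotypes on both sides; reference populations present in the
    # panel are screened, frequency-only references are skipped.
    panel_pops = set(panel.populations)
    fst_frames = []
    for focal in config.focal_populations:
        for ref_pop in ref_pops:
            if ref_pop in panel_pops:
                fst_frames.append(
                    wc_theta_from_genotypes(variants, panel, (focal, ref_pop))
                )
    fst_frames.append(wc_theta_from_genotypes(variants, panel, (focal_a, focal_b)))
    fst_table = pd.concat(fst_frames, ignore_index=True) if fst_frames else pd.DataFrame()
    high = (
        flag_high_fst(fst_table, config.fst_threshold, list(config.focal_populations))
        if len(fst_table)
        else set()
    )
    counts["high_fst"] = len(high)

    low_maf_sig = set()
    for frame in low_calls.values():
        if len(frame):
            low_maf_sig |= set(frame.loc[frame["significant"], "variant"])
    def _cat(frames):
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else calls[focal_a].head(0)

    all_calls_a = _cat([calls[focal_a], low_calls[focal_a]])
    all_calls_b = _cat([calls[focal_b], low_calls[focal_b]])
    classifications = classify_shared_unique(
        all_calls_a,
        all_calls_b,
        annotations,
        low_maf_variants=set(partition.low_maf),
    )
    classifications = apply_high_fst(classifications, high)
    summary = summarize_by_gene(classifications)
    for row in summary.itertuples(index=False):
        counts[f"class_{row.category}"] = int(row.n_variants)

    pca_coords = None
    try:
        pca_result = genotype_pca(variants, panel, k=config.pca_components)
        pca_coords = pca_result.coordinates
    except ValueError as exc:
        logger.warning("PCA skipped: %s", exc)

    # output location is deliberately left out so identical runs produce
    # byte-identical manifests wherever they are written
    config_dict = asdict(config)
    sim_section = config_dict.pop("simulate", None)
    config_dict.pop("out_dir", None)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in config_dict.items()
        },
        "simulate": sim_section,
        "reference_populations": ref_pops,
        "bonferroni": {
            "alpha": scheme.alpha,
            "n_variants": scheme.n_variants,
            "n_reference_pops": scheme.n_reference_pops,
            "adjusted_level": scheme.adjusted_level,
        },
        "counts": counts,
    }

    if write_artifacts:
        os.makedirs(config.out_dir, exist_ok=True)
        art = lambda name: os.path.join(config.out_dir, name)
        pio.write_report_table(freqs, art("frequencies.tsv"))
        pd.DataFrame(
            {"variant": partition.retained + partition.low_maf,
             "maf_partition": ["retained"] * len(partition.retained)
             + ["low_maf"] * len(partition.low_maf)}
        ).to_csv(art("maf_partition.tsv"), sep="\t", index=False)
        for focal in config.focal_populations:
            pio.write_report_table(calls[focal], art(f"chisq_{focal}.tsv"))
            pio.write_report_table(low_calls[focal], art(f"chisq_lowmaf_{focal}.tsv"))
        if len(fst_table):
            pio.write_report_table(fst_table, art("fst.tsv"))
        pio.write_report_table(classifications, art("classification.tsv"))
        summary.to_csv(art("gene_summary.tsv"), sep="\t", index=False)
        if pca_coords is not None:
            pio.write_report_table(
                pca_coords,
                art("pca.tsv"),
                float_formats={c: "{:.6f}" for c in pca_coords.columns if c.startswith("PC")},
            )
        with open(art("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return RunResult(
        variants=variants,
        panel=panel,
        frequencies=freqs,
        retained=partition.retained,
        low_maf=partition.low_maf,
        calls=calls,
        low_maf_calls=low_calls,
        fst=fst_table,
        high_fst=high,
        classifications=classifications,
        gene_summary=summary,
        pca=pca_coords,
        manifest=manifest,
    )
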