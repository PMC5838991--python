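"""Synthetic targeted-panel cohort generator with full truth labels.

Emulates the study conditions of a tumor-only panel-sequencing cohort:
15 tumors sequenced at ~300x and 53 platform-matched normals at ~700x on a
multi-gene panel, with

* true somatic variants (VAF ~ Beta, mean ~0.2; a fraction flagged as
  COSMIC hotspots),
* germline variants at population frequencies straddling the 1% filter
  threshold (a two-point mixture: common ~5%, rare ~0.01%),
* recurrent low-VAF sequencing artifacts shared across normals (and
  injected into a fraction of tumors), plus sporadic artifacts below the
  recurrence threshold,
* false positives inside repeat-masked regions, and
* per-gene copy-number shifts (log2 in {-1, 0, +1}) with multiplicative
  coverage noise.

Every emitted variant carries exactly one origin label, so the filtering
cascade can be scored against construction truth.  Each gene's span is
partitioned into disjoint position pools (somatic / germline / artifact /
repeat), and each normal draws its private germline positions from its own
stripe of the germline pool; recurrent artifact sites are planted in
strictly more than 20% of normals and sporadic ones in at most 20%, so the
panel-of-normals blacklist recovers exactly the recurrent sites by
construction.  Identical seed and config give byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import io as eio
from .filters import KEEP_CLASSES, CascadeConfig, filter_evidence_tier
from .model import (
    ClinicalRecord,
    RegionSet,
    Sift,
    VariantCall,
    VariantClass,
    DEFAULT_GENE_GROUPS,
)

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate_cohort",
           "evaluate_against_truth", "EvaluationResult", "load_bundle"]

_BASES = "ACGT"

_CLASS_PROBS = {
    VariantClass.missense: 0.55,
    VariantClass.stopgain: 0.10,
    VariantClass.frameshift_indel: 0.10,
    VariantClass.nonframeshift_indel: 0.05,
    VariantClass.splice: 0.05,
    VariantClass.synonymous: 0.15,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults are the emulated study conditions."""

    seed: int = 1
    n_tumors: int = 15
    n_normals: int = 53
    panel_genes: int = 60
    bins_per_gene: int = 50
    bin_size: int = 100
    mean_depth: int = 300            # tumor sequencing depth
    normal_mean_depth: int = 700     # normal-cohort sequencing depth
    germline_per_patient: float = 10.0
    germline_common_fraction: float = 0.7
    common_popfreq: float = 0.05
    rare_popfreq: float = 0.0001
    somatic_per_patient: float = 12.0
    somatic_vaf_alpha: float = 2.0   # Beta(2, 8): mean VAF 0.2
    somatic_vaf_beta: float = 8.0
    hotspot_fraction: float = 0.3
    artifact_sites: int = 30
    recurrent_artifact_fraction: float = 0.5
    recurrent_normal_fraction: float = 0.30  # > 0.20 by construction
    sporadic_normal_fraction: float = 0.10   # <= 0.20 by construction
    artifact_tumor_fraction: float = 0.3
    repeat_fraction: float = 0.10
    repeat_artifacts_per_patient: float = 2.0
    cnv_genes_per_patient: int = 3
    cnv_noise_sd: float = 0.1

    def validate(self) -> None:
        counts = (self.n_tumors, self.n_normals, self.panel_genes,
                  self.bins_per_gene, self.bin_size, self.artifact_sites,
                  self.cnv_genes_per_patient)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if min(self.n_tumors, self.n_normals, self.panel_genes,
               self.bins_per_gene, self.bin_size) <= 0:
            raise ValueError("cohort/panel sizes must be positive")
        fracs = (self.germline_common_fraction, self.hotspot_fraction,
                 self.recurrent_artifact_fraction, self.recurrent_normal_fraction,
                 self.sporadic_normal_fraction, self.artifact_tumor_fraction,
                 self.repeat_fraction)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.repeat_fraction >= 0.3:
            raise ValueError("repeat_fraction must stay below 0.3 "
                             "(repeat block may not swallow the artifact pool)")
        span = self.bins_per_gene * self.bin_size
        if self.artifact_sites > self.panel_genes * max(1, self._pool(span, "artifact")[1]
                                                        - self._pool(span, "artifact")[0]):
            raise ValueError("more artifact sites than artifact-pool positions")
        if self.cnv_genes_per_patient > self.panel_genes:
            raise ValueError("cnv_genes_per_patient exceeds panel_genes")

    # position-pool partition of a gene span (offsets, half-open)
    def _pool(self, span: int, kind: str) -> tuple[int, int]:
        repeat_len = max(1, int(self.repeat_fraction * span))
        bounds = {
            "somatic": (0, int(0.4 * span)),
            "germline": (int(0.4 * span), int(0.7 * span)),
            "artifact": (int(0.7 * span), span - repeat_len),
            "repeat": (span - repeat_len, span),
        }
        return bounds[kind]


@dataclass
class SyntheticBundle:
    """In-memory cohort bundle; `write` materializes the on-disk layout."""

    config: SyntheticConfig
    tumor_tables: dict[str, list[VariantCall]]
    normal_tables: dict[str, list[VariantCall]]
    tumor_coverage: dict[str, pd.DataFrame]
    reference_coverage: pd.DataFrame
    panel_genes: list[tuple[str, int, int, str]]  # chrom, start, end, gene
    repeats: RegionSet
    clinical: list[ClinicalRecord]
    truth_variants: pd.DataFrame
    truth_cnv: pd.DataFrame
    truth_summary: pd.DataFrame

    @property
    def panel(self) -> RegionSet:
        return RegionSet([(c, s, e) for c, s, e, _ in self.panel_genes], label="panel")

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        (out / "tumors").mkdir(parents=True, exist_ok=True)
        (out / "normals").mkdir(exist_ok=True)
        (out / "coverage").mkdir(exist_ok=True)
        with open(out / "panel.bed", "w") as fh:
            for c, s, e, g in self.panel_genes:
                fh.write(f"{c}\t{s}\t{e}\t{g}\n")
        with open(out / "repeats.bed", "w") as fh:
            for c, s, e in self.repeats.intervals:
                fh.write(f"{c}\t{s}\t{e}\n")
        for pid, table in sorted(self.tumor_tables.items()):
            eio.write_variant_table(table, out / "tumors" / f"{pid}.tsv")
        for nid, table in sorted(self.normal_tables.items()):
            eio.write_variant_table(table, out / "normals" / f"{nid}.tsv")
        for pid, cov in sorted(self.tumor_coverage.items()):
            eio.write_coverage(cov, out / "coverage" / f"{pid}_tumor.tsv")
        eio.write_coverage(self.reference_coverage, out / "coverage" / "reference.tsv")
        eio.write_clinical_table(self.clinical, out / "clinical.tsv")
        self.truth_variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
        self.truth_cnv.to_csv(out / "truth_cnv.tsv", sep="\t", index=False)
        self.truth_summary.to_csv(out / "truth_summary.tsv", sep="\t", index=False)


def _gene_names(n: int) -> list[str]:
    named = sorted(set().union(*DEFAULT_GENE_GROUPS.values()))
    if n <= len(named):
        return named[:n]
    return named + [f"GENE{i:03d}" for i in range(1, n - len(named) + 1)]


def _gene_base(g: int, span: int) -> int:
    # one synthetic chromosome; gene spans separated by a gap
    return 10_000 + g * (span + 5_000)


def _snv_alleles(pos: int, rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[pos % 4]
    alt = _BASES[(pos + 1 + int(rng.integers(3))) % 4]
    if alt == ref:
        alt = _BASES[(pos + 2) % 4]
    return ref, alt


def _alleles_for_class(pos: int, vclass: VariantClass, rng: np.random.Generator
                       ) -> tuple[str, str]:
    ref, alt = _snv_alleles(pos, rng)
    if vclass is VariantClass.frameshift_indel:
        return ref + alt, ref  # 1-bp deletion
    if vclass is VariantClass.nonframeshift_indel:
        return ref + "ACG", ref  # 3-bp deletion
    return ref, alt


def _evidence_counts(vaf0: float, depth_mean: int, rng: np.random.Generator
                     ) -> tuple[float, int, int]:
    depth = max(30, int(rng.poisson(depth_mean)))
    alt = int(round(vaf0 * depth))
    alt = min(max(alt, 0), depth)
    return (alt / depth, alt, depth)


def _sample_class(rng: np.random.Generator) -> VariantClass:
    classes = list(_CLASS_PROBS)
    probs = np.array([_CLASS_PROBS[c] for c in classes])
    return classes[int(rng.choice(len(classes), p=probs / probs.sum()))]


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(),
    out_dir: Optional[Union[str, Path]] = None,
) -> SyntheticBundle:
    """Generate a fully-labeled cohort bundle (optionally written to disk)."""
    config.validate()
    cfg = config
    span = cfg.bins_per_gene * cfg.bin_size
    genes = _gene_names(cfg.panel_genes)
    chrom = "chr1"
    tumors = [f"P{i + 1:02d}" for i in range(cfg.n_tumors)]
    normals = [f"N{i + 1:02d}" for i in range(cfg.n_normals)]

    ss = np.random.SeedSequence(cfg.seed)
    rng_som, rng_germ, rng_art, rng_cov, rng_clin = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    truth_rows: list[dict] = []
    tumor_tables: dict[str, list[VariantCall]] = {p: [] for p in tumors}
    normal_tables: dict[str, list[VariantCall]] = {n: [] for n in normals}

    def record(v: VariantCall, origin: str, subtype: str = "") -> None:
        truth_rows.append(
            {"patient_id": v.patient_id, "chrom": v.chrom, "pos": v.pos,
             "ref": v.ref, "alt": v.alt, "gene": v.gene,
             "variant_class": v.variant_class.value, "vaf": v.vaf,
             "alt_reads": v.alt_reads, "depth": v.depth, "cosmic": v.cosmic,
             "origin": origin, "subtype": subtype}
        )

    # ---- somatic variants -------------------------------------------------
    som_lo, som_hi = cfg._pool(span, "somatic")
    pool = som_hi - som_lo
    for pid in tumors:
        k = int(rng_som.poisson(cfg.somatic_per_patient))
        flat = rng_som.choice(cfg.panel_genes * pool, size=min(k, cfg.panel_genes * pool),
                              replace=False)
        for idx in sorted(int(x) for x in flat):
            g, off = divmod(idx, pool)
            pos = _gene_base(g, span) + som_lo + off + 1  # 1-based
            vclass = _sample_class(rng_som)
            ref, alt = _alleles_for_class(pos, vclass, rng_som)
            vaf0 = float(rng_som.beta(cfg.somatic_vaf_alpha, cfg.somatic_vaf_beta))
            vaf, alt_reads, depth = _evidence_counts(vaf0, cfg.mean_depth, rng_som)
            if alt_reads == 0:
                continue
            v = VariantCall(
                patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=genes[g], variant_class=vclass, vaf=vaf,
                alt_reads=alt_reads, depth=depth,
                cosmic=bool(rng_som.random() < cfg.hotspot_fraction),
                sift=Sift.deleterious if rng_som.random() < 0.5 else Sift.neutral,
            )
            tumor_tables[pid].append(v)
            record(v, "somatic")

    # ---- germline variants ------------------------------------------------
    germ_lo, germ_hi = cfg._pool(span, "germline")
    gpool = germ_hi - germ_lo

    def make_germline(pid: str, pos: int, gene_idx: int, depth_mean: int,
                      rng: np.random.Generator) -> tuple[VariantCall, str]:
        common = bool(rng.random() < cfg.germline_common_fraction)
        freq = cfg.common_popfreq if common else cfg.rare_popfreq
        vaf0 = float(rng.beta(30, 30))  # heterozygous, centred on 0.5
        vaf, alt_reads, depth = _evidence_counts(vaf0, depth_mean, rng)
        ref, alt = _snv_alleles(pos, rng)
        v = VariantCall(
            patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=genes[gene_idx], variant_class=VariantClass.missense,
            vaf=vaf, alt_reads=alt_reads, depth=depth, cosmic=False,
            popfreq_1000g=freq * 0.9, popfreq_exac=freq,
            sift=Sift.neutral,
        )
        return v, ("common" if common else "rare")

    for pid in tumors:
        k = int(rng_germ.poisson(cfg.germline_per_patient))
        flat = rng_germ.choice(cfg.panel_genes * gpool,
                               size=min(k, cfg.panel_genes * gpool), replace=False)
        for idx in sorted(int(x) for x in flat):
            g, off = divmod(idx, gpool)
            pos = _gene_base(g, span) + germ_lo + off + 1
            v, subtype = make_germline(pid, pos, g, cfg.mean_depth, rng_germ)
            tumor_tables[pid].append(v)
            record(v, "germline", subtype)

    # private germline stripes for normals: each normal samples positions only
    # from its own stripe, so no germline key recurs across normals
    stripe = gpool // cfg.n_normals
    if stripe >= 1:
        for j, nid in enumerate(normals):
            k = int(rng_germ.poisson(cfg.germline_per_patient))
            flat = rng_germ.choice(cfg.panel_genes * stripe,
                                   size=min(k, cfg.panel_genes * stripe), replace=False)
            for idx in sorted(int(x) for x in flat):
                g, off = divmod(idx, stripe)
                pos = _gene_base(g, span) + germ_lo + j * stripe + off + 1
                v, _ = make_germline(nid, pos, g, cfg.normal_mean_depth, rng_germ)
                normal_tables[nid].append(v)

    # ---- artifact sites ---------------------------------------------------
    art_lo, art_hi = cfg._pool(span, "artifact")
    apool = art_hi - art_lo
    n_recurrent = int(round(cfg.artifact_sites * cfg.recurrent_artifact_fraction))
    flat_sites = rng_art.choice(cfg.panel_genes * apool, size=cfg.artifact_sites,
                                replace=False)
    # carrier counts chosen so recurrence strictly crosses (or stays under)
    # the 20% blacklist threshold by construction
    n_carrier_rec = max(math.floor(0.2 * cfg.n_normals) + 1,
                        int(round(cfg.recurrent_normal_fraction * cfg.n_normals)))
    n_carrier_spor = min(math.floor(0.2 * cfg.n_normals),
                         int(round(cfg.sporadic_normal_fraction * cfg.n_normals)))
    n_carrier_tum = int(round(cfg.artifact_tumor_fraction * cfg.n_tumors))

    for s_idx, flat in enumerate(sorted(int(x) for x in flat_sites)):
        g, off = divmod(flat, apool)
        pos = _gene_base(g, span) + art_lo + off + 1
        recurrent = s_idx < n_recurrent
        subtype = "recurrent" if recurrent else "sporadic"
        ref, alt = _snv_alleles(pos, rng_art)

        def make_artifact(pid: str, depth_mean: int) -> VariantCall:
            vaf0 = float(rng_art.uniform(0.015, 0.04))
            vaf, alt_reads, depth = _evidence_counts(vaf0, depth_mean, rng_art)
            return VariantCall(
                patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=genes[g], variant_class=VariantClass.missense,
                vaf=vaf, alt_reads=alt_reads, depth=depth, cosmic=False,
                sift=Sift.neutral,
            )

        n_carriers = n_carrier_rec if recurrent else n_carrier_spor
        for j in sorted(int(x) for x in
                        rng_art.choice(cfg.n_normals, n_carriers, replace=False)):
            normal_tables[normals[j]].append(make_artifact(normals[j],
                                                           cfg.normal_mean_depth))
        for j in sorted(int(x) for x in
                        rng_art.choice(cfg.n_tumors, n_carrier_tum, replace=False)):
            v = make_artifact(tumors[j], cfg.mean_depth)
            tumor_tables[tumors[j]].append(v)
            record(v, "artifact", subtype)

    # ---- repeat-region false positives ------------------------------------
    rep_lo, rep_hi = cfg._pool(span, "repeat")
    rpool = rep_hi - rep_lo
    for pid in tumors:
        k = int(rng_art.poisson(cfg.repeat_artifacts_per_patient))
        flat = rng_art.choice(cfg.panel_genes * rpool,
                              size=min(k, cfg.panel_genes * rpool), replace=False)
        for idx in sorted(int(x) for x in flat):
            g, off = divmod(idx, rpool)
            pos = _gene_base(g, span) + rep_lo + off + 1
            ref, alt = _snv_alleles(pos, rng_art)
            vaf0 = float(rng_art.beta(cfg.somatic_vaf_alpha, cfg.somatic_vaf_beta))
            vaf, alt_reads, depth = _evidence_counts(vaf0, cfg.mean_depth, rng_art)
            if alt_reads == 0:
                continue
            v = VariantCall(
                patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=genes[g], variant_class=VariantClass.missense,
                vaf=vaf, alt_reads=alt_reads, depth=depth, cosmic=False,
                sift=Sift.neutral,
            )
            tumor_tables[pid].append(v)
            record(v, "repeat_artifact")

    repeats = RegionSet(
        [(chrom, _gene_base(g, span) + rep_lo, _gene_base(g, span) + rep_hi)
         for g in range(cfg.panel_genes)],
        label="repeats",
    )
    panel_genes = [
        (chrom, _gene_base(g, span), _gene_base(g, span) + span, genes[g])
        for g in range(cfg.panel_genes)
    ]

    # ---- coverage / CNV ----------------------------------------------------
    bin_rows = []
    for g in range(cfg.panel_genes):
        base = _gene_base(g, span)
        for b in range(cfg.bins_per_gene):
            bin_rows.append((chrom, base + b * cfg.bin_size,
                             base + (b + 1) * cfg.bin_size, genes[g]))
    n_bins = len(bin_rows)
    bins_df = pd.DataFrame(bin_rows, columns=["chrom", "start", "end", "gene"])

    ref_cov = bins_df.assign(
        mean_coverage=np.round(
            cfg.normal_mean_depth
            * np.exp(rng_cov.normal(0.0, cfg.cnv_noise_sd, n_bins)),
            3,
        )
    )[["chrom", "start", "end", "mean_coverage", "gene"]]

    truth_cnv_rows = []
    tumor_coverage: dict[str, pd.DataFrame] = {}
    for pid in tumors:
        shifts = np.zeros(cfg.panel_genes)
        chosen = rng_cov.choice(cfg.panel_genes, cfg.cnv_genes_per_patient,
                                replace=False)
        signs = rng_cov.choice([-1.0, 1.0], cfg.cnv_genes_per_patient)
        shifts[chosen] = signs
        per_bin_shift = np.repeat(shifts, cfg.bins_per_gene)
        cov = np.round(
            cfg.mean_depth
            * (2.0 ** per_bin_shift)
            * np.exp(rng_cov.normal(0.0, cfg.cnv_noise_sd, n_bins)),
            3,
        )
        tumor_coverage[pid] = bins_df.assign(mean_coverage=cov)[
            ["chrom", "start", "end", "mean_coverage", "gene"]
        ]
        for g in range(cfg.panel_genes):
            state = "neutral" if shifts[g] == 0 else ("gain" if shifts[g] > 0 else "loss")
            truth_cnv_rows.append({"patient_id": pid, "gene": genes[g],
                                   "log2_shift": shifts[g], "state": state})

    # ---- clinical table -----------------------------------------------------
    def margins(choices: list, weights: list[int], n: int, rng) -> list:
        # proportional allocation of categories, remainder randomized
        total = sum(weights)
        counts = [int(n * w / total) for w in weights]
        while sum(counts) < n:
            counts[int(rng.integers(len(counts)))] += 1
        out = [c for c, k in zip(choices, counts) for _ in range(k)]
        rng.shuffle(out)
        return out

    sexes = margins(["male", "female"], [12, 3], cfg.n_tumors, rng_clin)
    stages = margins(["I", "II", "III"], [4, 7, 4], cfg.n_tumors, rng_clin)
    sites = margins(["upper", "mid", "lower"], [1, 7, 7], cfg.n_tumors, rng_clin)
    macros = margins(["polypoid", "ulcerating", "infiltrative"], [10, 1, 4],
                     cfg.n_tumors, rng_clin)
    clinical = []
    for i, pid in enumerate(tumors):
        clinical.append(
            ClinicalRecord(
                patient_id=pid, sex=sexes[i],
                age=int(rng_clin.integers(46, 71)),
                stage=stages[i], site=sites[i], macroscopic_type=macros[i],
                smoker=bool(sexes[i] == "male" and rng_clin.random() < 0.75),
                overall_survival_months=float(int(rng_clin.integers(1, 72))),
                alive=bool(rng_clin.random() < 0.5),
            )
        )

    # ---- truth summaries ----------------------------------------------------
    truth_variants = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "chrom", "pos", "ref", "alt", "gene",
                 "variant_class", "vaf", "alt_reads", "depth", "cosmic",
                 "origin", "subtype"],
    )
    tier = CascadeConfig()
    summary_rows = []
    for pid in tumors:
        eligible = sum(
            1 for v in tumor_tables[pid]
            if _truth_origin(truth_variants, v) == "somatic"
            and v.variant_class in KEEP_CLASSES
            and filter_evidence_tier(v, tier)
        )
        summary_rows.append({"patient_id": pid, "true_eligible_somatic": eligible})
    truth_summary = pd.DataFrame(summary_rows,
                                 columns=["patient_id", "true_eligible_somatic"])

    bundle = SyntheticBundle(
        config=cfg,
        tumor_tables=tumor_tables,
        normal_tables=normal_tables,
        tumor_coverage=tumor_coverage,
        reference_coverage=ref_cov,
        panel_genes=panel_genes,
        repeats=repeats,
        clinical=clinical,
        truth_variants=truth_variants,
        truth_cnv=pd.DataFrame(truth_cnv_rows,
                               columns=["patient_id", "gene", "log2_shift", "state"]),
        truth_summary=truth_summary,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _truth_origin(truth: pd.DataFrame, v: VariantCall) -> Optional[str]:
    hit = truth[
        (truth["patient_id"] == v.patient_id)
        & (truth["pos"] == v.pos)
        & (truth["alt"] == v.alt)
    ]
    if hit.empty:
        return None
    return str(hit["origin"].iloc[0])


@dataclass
class EvaluationResult:
    """Cascade performance against construction truth."""

    sensitivity: float              # kept / all above-threshold eligible somatic
    n_eligible_somatic: int
    n_eligible_kept: int
    removed_fraction: dict[str, float] = field(default_factory=dict)
    leakage: dict[str, int] = field(default_factory=dict)  # kept per unwanted class


def evaluate_against_truth(
    kept: list[VariantCall],
    truth: pd.DataFrame,
    config: CascadeConfig = CascadeConfig(),
) -> EvaluationResult:
    """Score a kept set against the generator's truth labels.

    Sensitivity is computed over somatic variants that meet both the
    functional keep-list and the evidence tier (below-threshold somatic
    variants are intended removals, not misses).  A kept variant absent
    from the truth table is an error.
    """
    truth = truth.copy()
    truth["_key"] = list(zip(truth["patient_id"].astype(str), truth["pos"],
                             truth["alt"]))
    by_key = truth.set_index("_key")
    kept_keys = set()
    for v in kept:
        k = (v.patient_id, v.pos, v.alt)
        if k not in by_key.index:
            raise ValueError(f"kept variant not present in truth labels: {k}")
        kept_keys.add(k)

    def is_eligible(row) -> bool:
        vclass = VariantClass(row["variant_class"])
        if vclass not in KEEP_CLASSES:
            return False
        if str(row["cosmic"]).strip().lower() in ("true", "1"):
            return (row["vaf"] > config.cosmic_min_vaf
                    and row["alt_reads"] >= config.cosmic_min_reads)
        return (row["vaf"] > config.noncosmic_min_vaf
                and row["alt_reads"] >= config.noncosmic_min_reads)

    n_eligible = 0
    n_eligible_kept = 0
    class_totals: dict[str, int] = {}
    class_kept: dict[str, int] = {}
    for k, row in by_key.iterrows():
        origin = str(row["origin"])
        subtype = str(row["subtype"]) if row["subtype"] else ""
        label = f"{origin}:{subtype}" if subtype else origin
        class_totals[label] = class_totals.get(label, 0) + 1
        if k in kept_keys:
            class_kept[label] = class_kept.get(label, 0) + 1
        if origin == "somatic" and is_eligible(row):
            n_eligible += 1
            if k in kept_keys:
                n_eligible_kept += 1

    removed_fraction = {
        label: 1.0 - class_kept.get(label, 0) / total
        for label, total in class_totals.items()
    }
    leakage = {
        label: class_kept.get(label, 0)
        for label in class_totals
        if not label.startswith("somatic")
    }
    return EvaluationResult(
        sensitivity=(n_eligible_kept / n_eligible) if n_eligible else float("nan"),
        n_eligible_somatic=n_eligible,
        n_eligible_kept=n_eligible_kept,
        removed_fraction=removed_fraction,
        leakage=leakage,
    )


def load_bundle(bundle_dir: Union[str, Path]) -> dict:
    """Load a written bundle back into the objects the pipeline consumes."""
    d = Path(bundle_dir)
    tumor_tables = {
        p.stem: eio.read_variant_table(p) for p in sorted((d / "tumors").glob("*.tsv"))
    }
    normal_tables = {
        p.stem: eio.read_variant_table(p) for p in sorted((d / "normals").glob("*.tsv"))
    }
    tumor_coverage = {
        p.stem.removesuffix("_tumor"): eio.read_coverage(p)
        for p in sorted((d / "coverage").glob("*_tumor.tsv"))
    }
    return {
        "tumor_tables": tumor_tables,
        "normal_tables": normal_tables,
        "tumor_coverage": tumor_coverage,
        "reference_coverage": eio.read_coverage(d / "coverage" / "reference.tsv"),
        "panel": eio.read_bed(d / "panel.bed", label="panel"),
        "panel_genes": eio.read_gene_bed(d / "panel.bed"),
        "repeats": (eio.read_bed(d / "repeats.bed", label="repeats")
                    if (d / "repeats.bed").exists() else None),
        "clinical": eio.read_clinical_table(d / "clinical.tsv"),
        "truth_variants": pd.read_csv(d / "truth_variants.tsv", sep="\t",
                                      keep_default_na=False),
        "truth_cnv": pd.read_csv(d / "truth_cnv.tsv", sep="\t"),
        "truth_summary": pd.read_csv(d / "truth_summary.tsv", sep="\t"),
    }
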