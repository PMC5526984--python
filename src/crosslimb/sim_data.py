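"""Synthetic two-species limb-bud RNA-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial gene counts for four groups (emu fore/hind,
chicken fore/hind), gene-wise multiplicative species biases applied to all
emu samples, shared tissue (fore-vs-hind) effects, and planted
species-by-tissue interaction effects. A second stage fragments the emu gene
counts into Corset-style assembly loci with BLAST-like hit tables (including
chimeric and unannotatable loci), and a third stage produces a mis-expression
experiment (treated vs control wing buds) with a female-specific marker gene
for sex inference.

Counts follow NB(mu, phi) with Var = mu + phi*mu^2. On the log2 scale the
mean model for the cross-species design is::

    log2 mu_gi = baseline_g + bias_g*[species=emu] + tissue_g*[tissue=fore]
                 + delta_g*[species=emu AND tissue=fore] + log2 sizefactor_i

where the per-sample size factor scales the expected column total to a
library-size target drawn uniformly from ``lib_size_range``. Because the
species bias enters both emu tissues equally it cancels from the fore/hind
ratio — the property that makes the interaction contrast, but not direct
cross-species contrasts, interpretable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crosslimb.io import BLAST6_COLUMNS

SPECIES = ("emu", "chicken")
TISSUES = ("fore", "hind")

#: log10 e-value windows for simulated hits: true homology hits fall strictly
#: below the conventional 1e-5 cutoff, spurious hits at or above it.
TRUE_HIT_LOG10E = (-50.0, -6.0)
SPURIOUS_HIT_LOG10E = (-5.0, 2.0)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedEffect:
    """A gene carrying a planted species-by-tissue interaction effect.

    ``delta`` is the log2 interaction effect (positive = up in emu forelimb
    relative to what the species and tissue main effects predict).
    ``baseline_log2`` optionally overrides the drawn baseline, e.g. to model
    a gene expressed essentially only in the emu forelimb.
    """

    gene_index: int
    delta: float
    baseline_log2: float | None = None


@dataclass
class SimConfig:
    """Parameters of the synthetic data generator.

    Defaults mirror the real study's shape: 2 replicate pools per group
    (8 samples), NB dispersion 0.1, gene-wise emu bias with sd 1 log2 unit,
    and library-size targets around forty million reads per sample, the
    depth the limb-bud libraries were sequenced to.
    """

    n_genes: int = 1000
    replicates: int = 2
    baseline_log2_mean: tuple[float, float] = (4.0, 2.0)  # (mean, sd), log2 scale
    dispersion: float = 0.1
    species_bias_sd: float = 1.0
    tissue_effect_sd: float = 0.5
    lib_size_range: tuple[float, float] = (3.2e7, 4.8e7)  # ~40M reads/sample
    planted: list[PlantedEffect] = field(default_factory=list)
    n_split_loci_mean: float = 2.0
    contigs_per_locus_mean: float = 1.5
    chimera_rate: float = 0.05
    unannotated_rate: float = 0.1
    seed: int = 0
    # mis-expression design
    misexpr_n_control: int = 3
    misexpr_n_treated: int = 3
    misexpr_sexes: tuple[str, ...] | None = None  # control samples first
    misexpr_target_log2fc: float = 6.0
    misexpr_sex_effects: list[tuple[int, float]] = field(default_factory=list)
    hintw_cpm: float = 100.0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        if self.dispersion <= 0:
            raise ConfigurationError("NB dispersion must be > 0")
        for name in ("chimera_rate", "unannotated_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.chimera_rate + self.unannotated_rate > 1.0:
            raise ConfigurationError("chimera_rate + unannotated_rate must be <= 1")
        lo, hi = self.lib_size_range
        if not 0 < lo <= hi:
            raise ConfigurationError("lib_size_range must satisfy 0 < min <= max")
        if self.n_split_loci_mean < 1:
            raise ConfigurationError("n_split_loci_mean must be >= 1")
        for p in self.planted:
            if not 0 <= p.gene_index < self.n_genes:
                raise ConfigurationError(f"planted gene_index {p.gene_index} out of range")
        if min(self.misexpr_n_control, self.misexpr_n_treated) < 2:
            raise ConfigurationError("mis-expression design needs >= 2 samples per arm")
        if self.misexpr_sexes is not None:
            n = self.misexpr_n_control + self.misexpr_n_treated
            if len(self.misexpr_sexes) != n:
                raise ConfigurationError(f"misexpr_sexes must list {n} entries")
            bad = set(self.misexpr_sexes) - {"male", "female"}
            if bad:
                raise ConfigurationError(f"unknown sexes: {sorted(bad)}")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth paired with a simulated dataset.

    ``genes``: per-gene baseline, species bias, tissue effect and interaction
    delta (or treatment/sex effects for the mis-expression design).
    ``samples``: per-sample group labels, library-size target and sex.
    ``loci``: filled by :func:`simulate_assembly` — parent gene, count
    proportion, contig count and annotation-fate status per locus.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    loci: pd.DataFrame | None = None


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_gene_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw NB gene-level counts for the 2x2 species-by-tissue design.

    Returns ``(emu_counts, chicken_counts, sample_sheet, truth)``. Counts are
    gene x sample integer DataFrames (one per species, sharing the gene
    index); the sample sheet has columns ``sample, species, tissue,
    replicate``. Identical config and seed give byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = _gene_ids(n)

    mu0, sd0 = config.baseline_log2_mean
    baseline = rng.normal(mu0, sd0, size=n)
    bias = rng.normal(0.0, config.species_bias_sd, size=n)
    tissue = rng.normal(0.0, config.tissue_effect_sd, size=n)
    delta = np.zeros(n)
    for p in config.planted:
        delta[p.gene_index] = p.delta
        if p.baseline_log2 is not None:
            baseline[p.gene_index] = p.baseline_log2

    rows = []
    for species in SPECIES:
        for tis in TISSUES:
            for rep in range(1, config.replicates + 1):
                prefix = ("E" if species == "emu" else "C") + ("F" if tis == "fore" else "H")
                rows.append((f"{prefix}_{rep}", species, tis, rep))
    samples = pd.DataFrame(rows, columns=["sample", "species", "tissue", "replicate"])

    lo, hi = config.lib_size_range
    lib_targets = rng.uniform(lo, hi, size=len(samples))
    # one fixed reference total (baseline expression) normalizes every sample,
    # so per-gene expected ratios between groups equal the planted effects
    # exactly; realized column totals then deviate from the target only by a
    # bounded composition factor, which is irrelevant to the contrasts.
    ref_total = np.exp2(baseline).sum()

    counts = {s: {} for s in SPECIES}
    for i, row in samples.iterrows():
        log2_rel = baseline.copy()
        if row.species == "emu":
            log2_rel += bias
        if row.tissue == "fore":
            log2_rel += tissue
            if row.species == "emu":
                log2_rel += delta
        rel = np.exp2(log2_rel)
        mu = rel * (lib_targets[i] / ref_total)
        phi = config.dispersion
        c = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
        counts[row.species][row["sample"]] = c

    emu = pd.DataFrame(counts["emu"], index=pd.Index(genes, name="gene_id"))
    chick = pd.DataFrame(counts["chicken"], index=pd.Index(genes, name="gene_id"))

    truth_genes = pd.DataFrame(
        {
            "baseline_log2": baseline,
            "species_bias": bias,
            "tissue_effect": tissue,
            "delta": delta,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth_samples = samples.assign(lib_target=lib_targets).set_index("sample")
    return emu, chick, samples, SimTruth(genes=truth_genes, samples=truth_samples)


def _fill_blast6(qseqid, sseqid, evalue, rng) -> dict:
    """One plausible outfmt-6 row; only qseqid/sseqid/evalue/bitscore matter."""
    length = int(rng.integers(80, 1200))
    pident = float(np.round(rng.uniform(60, 100), 2))
    log10e = np.log10(evalue) if evalue > 0 else -180.0
    bitscore = float(np.round(max(25.0, -2.0 * log10e + rng.uniform(0, 20)), 1))
    return {
        "qseqid": qseqid,
        "sseqid": sseqid,
        "pident": pident,
        "length": length,
        "mismatch": int(rng.integers(0, length // 4 + 1)),
        "gapopen": int(rng.integers(0, 5)),
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": evalue,
        "bitscore": bitscore,
    }


def simulate_assembly(
    gene_counts: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Fragment gene counts into assembly loci with BLAST-like hit tables.

    Each gene is split across 1+ loci by a multinomial draw with Dirichlet
    proportions; each locus owns >= 1 contig. A locus is independently marked
    chimeric (its contigs' best hits name two distinct genes, both below the
    e-value cutoff) with probability ``chimera_rate``, or unannotatable (hits
    only at/above the cutoff, or none) with probability ``unannotated_rate``;
    otherwise its contigs hit the parent gene strictly below the cutoff.

    Returns ``(locus_counts, cluster_map, hits)`` where ``cluster_map`` is a
    contig->locus Series and ``hits`` a 12-column outfmt-6 DataFrame.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    genes = list(gene_counts.index)
    gene_arr = np.asarray(genes)
    n_samples = gene_counts.shape[1]
    count_arr = gene_counts.to_numpy()

    locus_rows = []
    locus_counts = []
    cluster_contigs = []
    cluster_loci = []
    hit_rows = []
    locus_idx = 0

    e_true_lo, e_true_hi = TRUE_HIT_LOG10E
    e_spur_lo, e_spur_hi = SPURIOUS_HIT_LOG10E

    for gi, gene in enumerate(genes):
        n_loci = 1 + rng.poisson(config.n_split_loci_mean - 1.0)
        props = rng.dirichlet(np.full(n_loci, 5.0))
        # multinomial split of each sample's counts by the locus proportions
        split = np.empty((n_loci, n_samples), dtype=np.int64)
        for j in range(n_samples):
            split[:, j] = rng.multinomial(count_arr[gi, j], props)

        for k in range(n_loci):
            locus_id = f"Cluster-{locus_idx}"
            locus_idx += 1
            u = rng.uniform()
            if u < config.chimera_rate:
                status = "chimeric"
            elif u < config.chimera_rate + config.unannotated_rate:
                status = "unannotated"
            else:
                status = "clean"

            n_contigs = 1 + rng.poisson(config.contigs_per_locus_mean - 1.0)
            if status == "chimeric":
                n_contigs = max(2, n_contigs)
            contigs = [f"{locus_id}_ctg{c}" for c in range(n_contigs)]
            cluster_contigs.extend(contigs)
            cluster_loci.extend([locus_id] * n_contigs)

            partner = ""
            if status == "clean":
                for ctg in contigs:
                    ev = 10.0 ** rng.uniform(e_true_lo, e_true_hi)
                    hit_rows.append(_fill_blast6(ctg, gene, ev, rng))
                    # occasional spurious extra hit (to some other gene),
                    # removed by the e-value filter
                    if rng.uniform() < 0.3 and len(gene_arr) > 1:
                        other = gene
                        while other == gene:
                            other = gene_arr[rng.integers(len(gene_arr))]
                        ev2 = 10.0 ** rng.uniform(e_spur_lo, e_spur_hi)
                        hit_rows.append(_fill_blast6(ctg, other, ev2, rng))
            elif status == "chimeric":
                other = gene
                while other == gene:
                    other = gene_arr[rng.integers(len(gene_arr))]
                partner = other
                for c, ctg in enumerate(contigs):
                    target = gene if c % 2 == 0 else other
                    ev = 10.0 ** rng.uniform(e_true_lo, e_true_hi)
                    hit_rows.append(_fill_blast6(ctg, target, ev, rng))
            else:  # unannotated: sub-threshold evidence never appears
                for ctg in contigs:
                    if rng.uniform() < 0.5:
                        other = gene_arr[rng.integers(len(gene_arr))]
                        ev = 10.0 ** rng.uniform(e_spur_lo, e_spur_hi)
                        hit_rows.append(_fill_blast6(ctg, other, ev, rng))

            locus_counts.append(split[k])
            locus_rows.append(
                {
                    "locus_id": locus_id,
                    "parent_gene": gene,
                    "proportion": props[k],
                    "n_contigs": n_contigs,
                    "status": status,
                    "partner_gene": partner,
                }
            )

    loci = pd.DataFrame(locus_rows).set_index("locus_id")
    locus_count_df = pd.DataFrame(
        np.vstack(locus_counts), index=loci.index.copy(), columns=gene_counts.columns
    )
    cluster_map = pd.Series(
        cluster_loci, index=pd.Index(cluster_contigs, name="contig_id"), name="locus_id"
    )
    hits = pd.DataFrame(hit_rows, columns=BLAST6_COLUMNS)
    truth.loci = loci
    return locus_count_df, cluster_map, hits


DEFAULT_MISEXPR_SEXES = ("female", "male", "female", "male", "female", "male")

HINTW_ID = "HINTW"
MISEXPR_TARGET_ID = "NKX2-5"


def simulate_misexpression(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the mis-expression experiment: treated vs control wing buds.

    The count matrix contains a female-specific marker row (``HINTW``, mean
    ``hintw_cpm`` CPM in females, structurally zero in males), a designated
    target gene (``NKX2-5``) with planted treatment effect
    ``misexpr_target_log2fc``, optional sex-affected genes, and NB background
    genes. Returns ``(counts, sample_sheet, truth)``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    n_ctrl, n_trt = config.misexpr_n_control, config.misexpr_n_treated
    sexes = config.misexpr_sexes or DEFAULT_MISEXPR_SEXES[: n_ctrl + n_trt]
    if len(sexes) != n_ctrl + n_trt:
        raise ConfigurationError("misexpr_sexes length does not match the design")

    names = [f"ctrl_{i+1}" for i in range(n_ctrl)] + [f"nkx_{i+1}" for i in range(n_trt)]
    treatment = ["control"] * n_ctrl + ["misexpression"] * n_trt
    samples = pd.DataFrame(
        {
            "sample": names,
            "treatment": treatment,
            "replicate": list(range(1, n_ctrl + 1)) + list(range(1, n_trt + 1)),
            "sex": list(sexes),
        }
    )

    n = config.n_genes
    genes = _gene_ids(n)
    mu0, sd0 = config.baseline_log2_mean
    baseline = rng.normal(mu0, sd0, size=n)
    treat_fc = np.zeros(n)
    treat_fc[0] = config.misexpr_target_log2fc  # gene 0 is the NKX2-5 analogue
    sex_fc = np.zeros(n)
    for idx, eff in config.misexpr_sex_effects:
        if not 0 <= idx < n:
            raise ConfigurationError(f"sex-effect gene index {idx} out of range")
        sex_fc[idx] = eff

    lo, hi = config.lib_size_range
    lib_targets = rng.uniform(lo, hi, size=len(samples))
    phi = config.dispersion
    ref_total = np.exp2(baseline).sum()

    cols = {}
    for i, row in samples.iterrows():
        log2_rel = baseline.copy()
        if row.treatment == "misexpression":
            log2_rel += treat_fc
        if row.sex == "female":
            log2_rel += sex_fc
        rel = np.exp2(log2_rel)
        mu = rel * (lib_targets[i] / ref_total)
        c = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
        # female-specific marker: fixed CPM in females, structural zero in males
        if row.sex == "female":
            mu_w = config.hintw_cpm * 1e-6 * lib_targets[i]
            w = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu_w))
        else:
            w = 0
        cols[row["sample"]] = np.concatenate([c, [w]])

    index = pd.Index(genes + [HINTW_ID], name="gene_id")
    counts = pd.DataFrame(cols, index=index).rename(index={genes[0]: MISEXPR_TARGET_ID})

    truth_genes = pd.DataFrame(
        {
            "baseline_log2": np.concatenate([baseline, [np.nan]]),
            "treatment_log2fc": np.concatenate([treat_fc, [0.0]]),
            "sex_log2fc": np.concatenate([sex_fc, [np.nan]]),
        },
        index=index,
    ).rename(index={genes[0]: MISEXPR_TARGET_ID})
    truth_samples = samples.assign(lib_target=lib_targets).set_index("sample")
    return counts, samples, SimTruth(genes=truth_genes, samples=truth_samples)
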