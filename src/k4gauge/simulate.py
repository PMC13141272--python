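"""Synthetic data generator for the whole pipeline.

Emulates the statistical structure of a spike-in ChIP-seq + RNA-seq study of
H3K4 methylation in worm embryos, so every downstream stage (normalisation,
peak classification, metaprofiles, chromosome statistics, DEG summaries) can
run and be validated without any external download.

What is modelled
----------------
* A toy genome (six 1-Mb chromosomes I-V and X by default).
* TSS anchors and enhancer intervals placed on a coarse grid.
* Per-mark coverage shapes: H3K4me3 forms a double peak flanking the TSS
  (the downstream peak slightly higher), H3K4me2 a broad promoter dome, and
  H3K4me1 a valley at the TSS with flanking enrichment plus a strong central
  peak at enhancers. Genotype effects are multiplicative factors per
  (genotype, mark, feature class): the rbbp-5-like genotype depletes all
  marks nearly to background; the wdr-5-like genotype strongly reduces me3,
  reduces me2 at TSS while increasing it at enhancers, and increases me1.
* Spike-in read counts from an immunoprecipitation composition model:
  foreign chromatin is added at a fixed fraction of total chromatin, so the
  foreign share of sequenced reads grows as the target mark is depleted.
* DESeq2-style differential-expression result tables with designated up /
  down / null genes, lognormal expression, and internally consistent
  per-condition means.

Randomness is drawn from named streams derived from one master seed, so
adding or reordering stages never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib
from copy import deepcopy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .genome import GenomeModel, default_toy_genome
from .tracks import CoverageTrack, n_bins

MARKS = ("me1", "me2", "me3")

# Multiplicative (genotype, mark, feature class) factors relative to wild type.
DEFAULT_MARK_EFFECTS: dict[str, dict[str, dict[str, float]]] = {
    "wt": {m: {"tss": 1.0, "enhancer": 1.0} for m in MARKS},
    "wdr5": {
        "me3": {"tss": 0.25, "enhancer": 0.25},
        "me2": {"tss": 0.5, "enhancer": 1.6},
        "me1": {"tss": 1.5, "enhancer": 1.3},
    },
    "rbbp5": {m: {"tss": 0.05, "enhancer": 0.05} for m in MARKS},
}

# Coverage shape parameters per mark: (feature class -> list of Gaussian
# components (offset bp, sd bp, amplitude)).  Offsets for TSS shapes are in
# the direction of transcription; the me3 downstream peak is 30% higher.
_SHAPES: dict[str, dict[str, list[tuple[float, float, float]]]] = {
    "me3": {
        "tss": [(-200.0, 150.0, 300.0), (200.0, 150.0, 390.0)],
        "enhancer": [(0.0, 200.0, 30.0)],
    },
    "me2": {
        "tss": [(0.0, 400.0, 150.0)],
        "enhancer": [(0.0, 200.0, 80.0)],
    },
    "me1": {
        "tss": [(-400.0, 200.0, 80.0), (400.0, 200.0, 80.0)],
        "enhancer": [(0.0, 150.0, 150.0)],
    },
}

_BACKGROUND_LEVEL = 1.0  # intensity units per bin

# Per-TSS heterogeneity: roughly half of genes carry high promoter H3K4me3
# (with the me1 valley), the rest are me3-low with relatively more me1 —
# the bimodal structure the High/Low clustering step is meant to recover.
_ME3_LOW_FRACTION = 0.5
_CLASS_FACTORS = {  # mark -> (me3-high class, me3-low class) TSS multipliers
    "me3": (1.0, 0.1),
    "me2": (1.0, 0.6),
    "me1": (0.4, 1.2),
}
_TSS_STRENGTH_SD = 0.3  # lognormal sd of per-gene promoter strength


def tss_classes(n_tss: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Planted per-TSS ground truth: me3-low membership and promoter strength.

    Deterministic for a given master seed, shared across marks and genotypes
    so the same gene keeps its class in every track.
    """
    rng = stream(seed, "tss-classes")
    low = rng.random(n_tss) < _ME3_LOW_FRACTION
    strength = rng.lognormal(0.0, _TSS_STRENGTH_SD, n_tss)
    return low, strength


def stream(seed: int, name: str) -> np.random.Generator:
    """Named random stream: independent of every other name for the same seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class DegParams:
    """Parameters of the synthetic differential-expression table.

    Default fractions follow the structure printed for the wdr-5-like
    mutant: roughly twice as many up- as down-regulated genes, with
    down-regulated genes drawn from a higher wild-type expression stratum
    (``down_log_shift`` on the natural-log scale of baseMean).
    """

    n_genes: int = 5000
    frac_up: float = 0.11
    frac_down: float = 0.055
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    basemean_log_mean: float = 4.0
    basemean_log_sd: float = 1.0
    x_gene_fraction: float = 0.15
    down_log_shift: float = 1.0

    def __post_init__(self) -> None:
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if not (0 <= self.x_gene_fraction <= 1):
            raise ValueError("x_gene_fraction must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    bin_size: int = 10
    mark_effects: dict = field(default_factory=lambda: deepcopy(DEFAULT_MARK_EFFECTS))
    depth: int = 1_000_000
    spike_fraction: float = 0.05
    deg_params: DegParams = field(default_factory=DegParams)

    def __post_init__(self) -> None:
        if not (0 < self.spike_fraction < 1):
            raise ValueError("spike_fraction must be in (0, 1)")
        if self.bin_size <= 0 or self.depth <= 0:
            raise ValueError("bin_size and depth must be positive")
        for genotype, marks in self.mark_effects.items():
            for mark, classes in marks.items():
                for cls, factor in classes.items():
                    if factor < 0:
                        raise ValueError(
                            f"negative effect factor for {genotype}/{mark}/{cls}")


# -- features ---------------------------------------------------------------

def simulate_features(genome: GenomeModel, n_tss: int, n_enh: int, seed: int,
                      enhancer_width: int = 400, edge_clearance: int = 6000,
                      grid_spacing: int = 2000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place TSS anchors and enhancer intervals on a coarse genomic grid.

    Anchors are sampled without replacement from a ``grid_spacing`` grid that
    keeps ``edge_clearance`` bp away from chromosome ends, so every anchor
    admits a +/-5 kb window.  TSS and enhancers never share a grid position.
    """
    if n_tss < 0 or n_enh < 0:
        raise ValueError("feature counts must be non-negative")
    rng = stream(seed, "features")
    slots: list[tuple[str, int]] = []
    for name, length in genome.chromosomes:
        lo, hi = edge_clearance, length - edge_clearance
        if hi <= lo:
            continue
        slots.extend((name, int(p)) for p in range(lo, hi, grid_spacing))
    if n_tss + n_enh > len(slots):
        raise ValueError(
            f"genome too small: {n_tss + n_enh} features requested, "
            f"{len(slots)} placeable positions")
    order = rng.permutation(len(slots))
    chosen = [slots[i] for i in order[: n_tss + n_enh]]
    chosen.sort()

    pick = rng.permutation(len(chosen))
    tss_idx = sorted(pick[:n_tss])
    enh_idx = sorted(pick[n_tss:])

    strands = rng.choice(["+", "-"], size=n_tss)
    tss = pd.DataFrame(
        [{"chrom": chosen[i][0], "start": chosen[i][1], "end": chosen[i][1] + 1,
          "name": f"tss_{k}", "score": 0, "strand": strands[k]}
         for k, i in enumerate(tss_idx)], columns=kio.BED6_COLUMNS)
    half = enhancer_width // 2
    enh = pd.DataFrame(
        [{"chrom": chosen[i][0], "start": chosen[i][1] - half,
          "end": chosen[i][1] - half + enhancer_width,
          "name": f"enh_{k}", "score": 0, "strand": "."}
         for k, i in enumerate(enh_idx)], columns=kio.BED6_COLUMNS)
    return tss, enh


# -- coverage ---------------------------------------------------------------

def _check_mark_genotype(mark: str, genotype: str, config: SimConfig) -> None:
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    if genotype not in config.mark_effects:
        raise ValueError(f"genotype {genotype!r} has no entry in mark_effects")


def expected_intensity(genome: GenomeModel, tss: pd.DataFrame, enhancers: pd.DataFrame,
                       mark: str, genotype: str, config: SimConfig) -> dict[str, np.ndarray]:
    """Noise-free per-bin intensity field lambda (arbitrary units).

    Coverage is drawn as Poisson reads proportional to this field; tests and
    the spike model use it directly as ground truth.
    """
    _check_mark_genotype(mark, genotype, config)
    bs = config.bin_size
    lam = {name: np.full(n_bins(length, bs), _BACKGROUND_LEVEL, dtype=float)
           for name, length in genome.chromosomes}
    effects = config.mark_effects[genotype][mark]

    def add(chrom: str, center: float, components, scale: float, orient: int) -> None:
        arr = lam[chrom]
        for offset, sd, amp in components:
            mu = center + orient * offset
            sd_bins = sd / bs
            lo = max(0, int(mu / bs - 5 * sd_bins))
            hi = min(len(arr), int(mu / bs + 5 * sd_bins) + 1)
            if hi <= lo:
                continue
            centers = (np.arange(lo, hi) + 0.5) * bs
            arr[lo:hi] += scale * amp * np.exp(-0.5 * ((centers - mu) / sd) ** 2)

    low, strength = tss_classes(len(tss), config.seed)
    hi_f, lo_f = _CLASS_FACTORS[mark]
    for k, (_, row) in enumerate(tss.iterrows()):
        orient = -1 if row["strand"] == "-" else 1
        class_factor = (lo_f if low[k] else hi_f) * strength[k]
        add(row["chrom"], row["start"] + 0.5, _SHAPES[mark]["tss"],
            effects.get("tss", 0.0) * class_factor, orient)
    for _, row in enhancers.iterrows():
        mid = (row["start"] + row["end"]) / 2
        add(row["chrom"], mid, _SHAPES[mark]["enhancer"],
            effects.get("enhancer", 0.0), 1)
    return lam


def effective_ip_material(genome: GenomeModel, tss: pd.DataFrame, enhancers: pd.DataFrame,
                          mark: str, genotype: str, config: SimConfig) -> float:
    """Total immunoprecipitated chromatin (sum of the intensity field)."""
    lam = expected_intensity(genome, tss, enhancers, mark, genotype, config)
    return float(sum(v.sum() for v in lam.values()))


def simulate_coverage(genome: GenomeModel, tss: pd.DataFrame, enhancers: pd.DataFrame,
                      mark: str, genotype: str, config: SimConfig,
                      depth: int | None = None) -> CoverageTrack:
    """Draw a raw-count coverage track: Poisson reads proportional to intensity."""
    _check_mark_genotype(mark, genotype, config)
    depth = config.depth if depth is None else int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    lam = expected_intensity(genome, tss, enhancers, mark, genotype, config)
    total = sum(v.sum() for v in lam.values())
    rng = stream(config.seed, f"coverage:{genotype}:{mark}")
    values = {c: rng.poisson(depth * v / total).astype(np.int64) for c, v in lam.items()}
    return CoverageTrack(bin_size=config.bin_size, values=values, normalisation="raw",
                         meta={"mark": mark, "genotype": genotype, "depth": depth})


# -- spike-in counts --------------------------------------------------------

def spike_read_fraction(depletion: float, spike_fraction: float) -> float:
    """Expected foreign-read share of a library under the composition model.

    The IP pool holds foreign chromatin (fixed share ``spike_fraction`` of the
    input, unaffected by genotype) plus target chromatin scaled by the
    genotype's ``depletion`` factor; reads split in proportion.
    """
    s = spike_fraction
    return s / (s + depletion * (1.0 - s))


def simulate_spikein_counts(true_depletion: dict[str, float], depths: dict[str, int],
                            spike_fraction: float, seed: int) -> pd.DataFrame:
    """Per-sample (target_reads, spike_reads) under the composition model."""
    if set(true_depletion) != set(depths):
        raise ValueError("true_depletion and depths must cover the same samples")
    for sample, f in true_depletion.items():
        if not (0 <= f <= 1):
            raise ValueError(f"depletion factor for {sample!r} must be in [0, 1]")
        if depths[sample] <= 0:
            raise ValueError(f"depth for {sample!r} must be positive")
    rng = stream(seed, "spikein")
    rows = []
    for sample in true_depletion:
        depth = int(depths[sample])
        p = spike_read_fraction(true_depletion[sample], spike_fraction)
        spike = int(rng.binomial(depth, p))
        rows.append({"sample_id": sample, "target_reads": depth - spike,
                     "spike_reads": spike})
    return pd.DataFrame(rows)


# -- differential-expression tables -----------------------------------------

def simulate_deg_table(config: SimConfig, genome: GenomeModel, label: str = "mut",
                       params: DegParams | None = None,
                       cooks_replicate: str | None = None,
                       cooks_outlier_frac: float = 0.02) -> pd.DataFrame:
    """DESeq2-style result table with designated up/down/null genes.

    Up/down genes get |log2FC| > 1 and padj < 0.05 by construction; null genes
    get log2FC near 0 and padj uniform on (0.05, 1].  Per-condition means are
    consistent: baseMeanB = baseMeanA * 2**log2FC and baseMean is their mean.
    The construction label is kept in ``sim_label`` as ground truth.
    """
    p = config.deg_params if params is None else params
    rng = stream(config.seed, f"deg:{label}")
    n = p.n_genes
    n_up = int(round(p.frac_up * n))
    n_down = int(round(p.frac_down * n))
    labels = np.array(["up"] * n_up + ["down"] * n_down + ["null"] * (n - n_up - n_down))

    log_mu = np.full(n, p.basemean_log_mean)
    log_mu[labels == "down"] += p.down_log_shift
    base_mean = rng.lognormal(mean=log_mu, sigma=p.basemean_log_sd)

    lfc = rng.normal(0.0, 0.15, size=n)
    magnitude = 1.0 + np.abs(rng.normal(p.lfc_mean - 1.0, p.lfc_sd, size=n))
    lfc[labels == "up"] = magnitude[labels == "up"]
    lfc[labels == "down"] = -magnitude[labels == "down"]

    padj = rng.uniform(0.05, 1.0, size=n)
    sig = labels != "null"
    padj[sig] = 10.0 ** rng.uniform(-8, np.log10(0.049), size=int(sig.sum()))

    # chromosome assignment comes from a universe-level stream, so tables for
    # different mutants over the same config share gene ids AND locations
    urng = stream(config.seed, f"deg-universe:{n}")
    is_x = urng.random(n) < p.x_gene_fraction
    chrom = np.where(is_x, genome.x_name,
                     urng.choice(genome.autosomes, size=n))

    a = 2.0 * base_mean / (1.0 + 2.0 ** lfc)
    b = a * 2.0 ** lfc
    table = pd.DataFrame({
        "gene_id": [f"gene_{i}" for i in range(n)],
        "chrom": chrom,
        "baseMean": base_mean,
        "baseMeanA": a,
        "baseMeanB": b,
        "log2FoldChange": lfc,
        "padj": padj,
        "sim_label": labels,
    })
    if cooks_replicate is not None:
        cooks = rng.uniform(0.0, 0.8, size=n)
        outliers = rng.random(n) < cooks_outlier_frac
        cooks[outliers] = rng.uniform(1.0, 5.0, size=int(outliers.sum()))
        table[f"cooks_{cooks_replicate}"] = cooks
    return table


def derive_double_mutant(single: pd.DataFrame, config: SimConfig,
                         restored_fraction: float = 0.2,
                         extra_deg_fraction: float = 0.05) -> pd.DataFrame:
    """Build a double-mutant table correlated with a single-mutant table.

    A seeded ``restored_fraction`` of the single mutant's constructed DEG
    revert to null behaviour (restored wild-type expression), while a seeded
    fraction of its null genes become DEG, so the double mutant ends up with
    at least as many DEG overall — the structure reported for the
    wdr-5-like single versus double mutant.
    """
    rng = stream(config.seed, "deg:double")
    out = single.copy()
    out["gene_id"] = single["gene_id"]  # shared universe: identical gene ids
    deg_idx = np.flatnonzero(single["sim_label"].to_numpy() != "null")
    null_idx = np.flatnonzero(single["sim_label"].to_numpy() == "null")
    n_restore = int(round(restored_fraction * len(deg_idx)))
    restore = rng.choice(deg_idx, size=n_restore, replace=False)
    out.loc[out.index[restore], "log2FoldChange"] = rng.normal(0, 0.15, n_restore)
    out.loc[out.index[restore], "padj"] = rng.uniform(0.05, 1.0, n_restore)
    out.loc[out.index[restore], "sim_label"] = "null"

    n_extra = int(round(extra_deg_fraction * len(null_idx)))
    extra = rng.choice(null_idx, size=n_extra, replace=False)
    direction = rng.choice([1.0, -1.0], size=n_extra)
    p = config.deg_params
    out.loc[out.index[extra], "log2FoldChange"] = direction * (
        1.0 + np.abs(rng.normal(p.lfc_mean - 1.0, p.lfc_sd, n_extra)))
    out.loc[out.index[extra], "padj"] = 10.0 ** rng.uniform(-8, np.log10(0.049), n_extra)
    out.loc[out.index[extra], "sim_label"] = np.where(direction > 0, "up", "down")

    # wild-type means are shared between contrasts; recompute the mutant side
    a = out["baseMeanA"]
    out["baseMeanB"] = a * 2.0 ** out["log2FoldChange"]
    out["baseMean"] = (out["baseMeanA"] + out["baseMeanB"]) / 2.0
    return out


# -- peaks ------------------------------------------------------------------

_PEAK_PARAMS = {
    # mark -> (tss base signal, enhancer base signal, (min,max) width bp)
    "me3": (8.0, 2.0, (600, 1600)),
    "me2": (6.0, 4.0, (2200, 4000)),
    "me1": (3.5, 7.0, (2200, 4000)),
}


def simulate_peaks(genome: GenomeModel, tss: pd.DataFrame, enhancers: pd.DataFrame,
                   mark: str, genotype: str, config: SimConfig,
                   n_other: int = 40) -> pd.DataFrame:
    """MACS2-style broadPeak calls at features plus background peaks.

    Peak strength scales with the genotype's effect factor, so a genotype
    that abolishes a mark yields peaks that fall below the post-filter
    signal threshold.
    """
    _check_mark_genotype(mark, genotype, config)
    rng = stream(config.seed, f"peaks:{genotype}:{mark}")
    effects = config.mark_effects[genotype][mark]
    tss_sig, enh_sig, (wmin, wmax) = _PEAK_PARAMS[mark]
    rows = []

    def emit(chrom: str, center: int, base_signal: float, factor: float) -> None:
        width = int(rng.integers(wmin, wmax))
        start = max(0, center - width // 2)
        end = min(genome.length(chrom), start + width)
        signal = base_signal * factor * rng.lognormal(0.0, 0.25)
        # q tracks signal strength: weak residual peaks fail q <= 0.005 too
        qneg = max(0.0, signal * 1.5 + rng.normal(0.0, 0.5))
        rows.append({"chrom": chrom, "start": start, "end": end,
                     "name": "", "score": int(min(1000, signal * 100)),
                     "strand": ".", "signalValue": round(signal, 4),
                     "pValue": round(qneg + 1.0, 4), "qValue": round(qneg, 4)})

    for _, row in tss.iterrows():
        emit(row["chrom"], int(row["start"]), tss_sig, effects.get("tss", 0.0))
    for _, row in enhancers.iterrows():
        emit(row["chrom"], int((row["start"] + row["end"]) // 2), enh_sig,
             effects.get("enhancer", 0.0))
    for _ in range(n_other):
        chrom, length = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        emit(chrom, int(rng.integers(10_000, length - 10_000)),
             float(rng.uniform(1.0, 6.0)), 1.0)

    peaks = pd.DataFrame(rows, columns=kio.BROADPEAK_COLUMNS)
    peaks["name"] = [f"{genotype}_{mark}_peak_{i}" for i in range(len(peaks))]
    peaks["mark"] = mark
    peaks["genotype"] = genotype
    return peaks


# -- gene models ------------------------------------------------------------

def simulate_gene_models(genome: GenomeModel, tss: pd.DataFrame,
                         gene_length: int = 2000, utr_length: int = 200,
                         n_exons: int = 3) -> pd.DataFrame:
    """Minimal gene models downstream of each TSS anchor.

    Long-form table (gene_id, chrom, strand, feature, start, end) with
    features UTR_exon / CDS / intron / TTS; strand follows the anchor.
    """
    rows = []
    for _, row in tss.iterrows():
        strand = row["strand"] if row["strand"] in "+-" else "+"
        chrom = row["chrom"]
        pos = int(row["start"])
        if strand == "+":
            g_start, g_end = pos, min(genome.length(chrom), pos + gene_length)
        else:
            g_start, g_end = max(0, pos - gene_length), pos + 1
        gid = f"g_{row['name']}"
        body = g_end - g_start
        utr = min(utr_length, body)
        if strand == "+":
            rows.append((gid, chrom, strand, "UTR_exon", g_start, g_start + utr))
            cursor = g_start + utr
            tts = g_end
        else:
            rows.append((gid, chrom, strand, "UTR_exon", g_end - utr, g_end))
            cursor = g_start
            tts = g_start
        # alternate CDS / intron blocks over the remaining body
        remaining = body - utr
        if remaining > 0:
            n_blocks = 2 * n_exons - 1
            edges = np.linspace(cursor, cursor + remaining, n_blocks + 1).astype(int)
            for k in range(n_blocks):
                feat = "CDS" if k % 2 == 0 else "intron"
                if edges[k + 1] > edges[k]:
                    rows.append((gid, chrom, strand, feat, int(edges[k]), int(edges[k + 1])))
        rows.append((gid, chrom, strand, "TTS", int(tts), int(tts) + 1))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "feature",
                                       "start", "end"])


# -- fixtures ---------------------------------------------------------------

def write_fixtures(outdir: str | Path, config: SimConfig | None = None,
                   genome: GenomeModel | None = None,
                   n_tss: int = 200, n_enh: int = 100,
                   genotypes: tuple[str, ...] = ("wt", "wdr5", "rbbp5")) -> dict[str, Path]:
    """Generate and write a complete, internally consistent fixture set.

    Writes chrom.sizes, feature BEDs, one bedGraph + broadPeak per
    (genotype, mark), a spike-in count table whose composition reflects each
    genotype's true signal loss, gene models, and DEG tables for a
    wdr-5-like mutant, an rbbp-5-like mutant (about five-fold fewer DEG, as
    in the study) and the derived double mutant.  Byte-identical for a given
    config.
    """
    config = SimConfig() if config is None else config
    genome = default_toy_genome() if genome is None else genome
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def note(key: str, path: Path) -> Path:
        manifest[key] = path
        return path

    kio.write_chrom_sizes(genome, note("chrom_sizes", outdir / "genome.chrom.sizes"))
    tss, enh = simulate_features(genome, n_tss, n_enh, seed=config.seed)
    kio.write_bed(tss, note("tss", outdir / "tss.bed"))
    kio.write_bed(enh, note("enhancers", outdir / "enhancers.bed"))

    gene_models = simulate_gene_models(genome, tss)
    kio.write_table(gene_models, note("gene_models", outdir / "gene_models.tsv"))

    # spike table: effective depletion = IP material relative to wild type
    spike_rows = []
    for mark in MARKS:
        material = {g: effective_ip_material(genome, tss, enh, mark, g, config)
                    for g in genotypes}
        top = max(material.values())  # a genotype can gain a mark, so scale to the max
        depletion = {f"{g}_{mark}": material[g] / top for g in genotypes}
        depths = {s: config.depth for s in depletion}
        counts = simulate_spikein_counts(depletion, depths, config.spike_fraction,
                                         seed=config.seed + zlib.crc32(mark.encode()) % 10_000)
        counts["genotype"] = [s.rsplit("_", 1)[0] for s in counts["sample_id"]]
        counts["mark"] = mark
        spike_rows.append(counts)
    spike = pd.concat(spike_rows, ignore_index=True)
    spike = spike[["sample_id", "genotype", "mark", "target_reads", "spike_reads"]]
    kio.write_table(spike, note("spike_counts", outdir / "spike_counts.tsv"))

    for _, row in spike.iterrows():
        g, mark = row["genotype"], row["mark"]
        track = simulate_coverage(genome, tss, enh, mark, g, config,
                                  depth=int(row["target_reads"]))
        kio.write_bedgraph(track, note(f"track_{g}_{mark}",
                                       outdir / f"coverage_{g}_{mark}.bedgraph"))
        peaks = simulate_peaks(genome, tss, enh, mark, g, config)
        kio.write_broadpeak(peaks, note(f"peaks_{g}_{mark}",
                                        outdir / f"peaks_{g}_{mark}.broadPeak"))

    # input-like chromatin: background only, no IP enrichment anywhere
    input_cfg = replace(config, mark_effects={
        **config.mark_effects,
        "input": {m: {"tss": 0.0, "enhancer": 0.0} for m in MARKS}})
    input_track = simulate_coverage(genome, tss, enh, "me3", "input", input_cfg)
    kio.write_bedgraph(input_track, note("track_input", outdir / "coverage_input.bedgraph"))

    wdr5_tab = simulate_deg_table(config, genome, label="wdr5",
                                  cooks_replicate="rep1")
    # The rbbp-5-like mutant's DEG structure: strong up-bias (11:1) with the
    # few down-regulated genes drawn from a much higher expression stratum,
    # so the net change stays mildly negative despite mostly up-regulation.
    rbbp5_params = replace(config.deg_params,
                           frac_up=0.033, frac_down=0.003, down_log_shift=2.5)
    rbbp5_tab = simulate_deg_table(config, genome, label="rbbp5", params=rbbp5_params,
                                   cooks_replicate="rep1")
    double_tab = derive_double_mutant(wdr5_tab, config)
    kio.write_table(wdr5_tab, note("deg_wdr5", outdir / "deg_wdr5.tsv"))
    kio.write_table(rbbp5_tab, note("deg_rbbp5", outdir / "deg_rbbp5.tsv"))
    kio.write_table(double_tab, note("deg_double", outdir / "deg_double.tsv"))
    return manifest
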