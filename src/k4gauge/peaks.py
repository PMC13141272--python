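"""Broad-peak post-filtering, regulatory classification and feature annotation.

Broad domains called for H3K4me1/me2 behave differently from the sharper
H3K4me3 promoter peaks, so the post-filter is mark-specific: me1/me2 peaks
must span at least 2 kb, me3 peaks at least 0.5 kb, and all peaks need fold
enrichment (signalValue) >= 3 at q <= 0.005.  Retained peaks are then placed
into four mutually exclusive regulatory categories by interval overlap with
promoter windows (TSS +/- 1 kb) and enhancers, and separately assigned one of
six genomic features (promoter-TSS, TTS, UTR exon, CDS, intron, intergenic)
by peak midpoint with a fixed precedence ladder.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# thresholds from the study, overridable per call
LENGTH_MIN = {"me1": 2000, "me2": 2000, "me3": 500}
SIGNAL_MIN = 3.0
Q_MAX = 0.005
Q_NEGLOG10_MIN = -np.log10(Q_MAX)  # broadPeak column 9 stores -log10(q)

CATEGORIES = ("Promoter_only", "Enhancer_only", "Promoter_Enhancer", "Other")
SIX_FEATURES = ("promoter-TSS", "TTS", "Exon (UTR)", "CDS", "intron", "intergenic")

# provenance only: the upstream peak-caller invocation these filters assume
MACS2_CALL_PARAMS = {"mode": "--broad", "broad_cutoff": 0.025, "q": 0.005}


# -- interval helpers -------------------------------------------------------

def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping half-open intervals into a sorted disjoint set."""
    if len(starts) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.asarray(out_s), np.asarray(out_e)


def overlaps_any(q_start: np.ndarray, q_end: np.ndarray,
                 iv_start: np.ndarray, iv_end: np.ndarray) -> np.ndarray:
    """Vector of bools: does each half-open query share >= 1 base with the
    (sorted, disjoint) interval set?"""
    if len(iv_start) == 0:
        return np.zeros(len(q_start), dtype=bool)
    # first interval whose end exceeds the query start; overlap iff it begins
    # before the query ends
    idx = np.searchsorted(iv_end, np.asarray(q_start), side="right")
    hit = idx < len(iv_start)
    out = np.zeros(len(q_start), dtype=bool)
    out[hit] = iv_start[idx[hit]] < np.asarray(q_end)[hit]
    return out


def _by_chrom(df: pd.DataFrame, start_col: str = "start",
              end_col: str = "end") -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in df.groupby("chrom"):
        out[chrom] = merge_intervals(grp[start_col].to_numpy(), grp[end_col].to_numpy())
    return out


# -- operations -------------------------------------------------------------

def filter_peaks(peaks: pd.DataFrame, length_min: dict[str, int] | None = None,
                 signal_min: float = SIGNAL_MIN, q_max: float = Q_MAX) -> pd.DataFrame:
    """Apply the mark-specific post-filter; boundaries are inclusive."""
    length_min = LENGTH_MIN if length_min is None else length_min
    unknown = set(peaks["mark"]) - set(length_min)
    if unknown:
        raise ValueError(f"unknown mark(s) {sorted(unknown)}")
    length = peaks["end"] - peaks["start"]
    min_len = peaks["mark"].map(length_min)
    keep = ((length >= min_len)
            & (peaks["signalValue"] >= signal_min)
            & (peaks["qValue"] >= -np.log10(q_max)))
    return peaks.loc[keep].copy()


def promoter_windows(tss: pd.DataFrame, halfwidth: int = 1000) -> pd.DataFrame:
    """Half-open windows [p - halfwidth, p + halfwidth) around TSS anchors."""
    out = tss.copy()
    pos = tss["start"]
    out["start"] = np.maximum(0, pos - halfwidth)
    out["end"] = pos + halfwidth
    return out


def classify_regulatory(peaks: pd.DataFrame, tss: pd.DataFrame,
                        enhancers: pd.DataFrame,
                        promoter_halfwidth: int = 1000) -> pd.DataFrame:
    """Assign each peak one of the four mutually exclusive categories.

    Overlap means any shared base with a promoter window (TSS +/- 1 kb,
    half-open) or an enhancer interval.  Peaks on chromosomes absent from
    both feature sets are classified Other.
    """
    prom = _by_chrom(promoter_windows(tss, promoter_halfwidth))
    enh = _by_chrom(enhancers)
    out = peaks.copy()
    category = np.full(len(peaks), "Other", dtype=object)
    for chrom, grp in peaks.groupby("chrom"):
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        in_prom = overlaps_any(qs, qe, *prom.get(chrom, ((), ())))
        in_enh = overlaps_any(qs, qe, *enh.get(chrom, ((), ())))
        loc = np.full(len(grp), "Other", dtype=object)
        loc[in_prom & ~in_enh] = "Promoter_only"
        loc[~in_prom & in_enh] = "Enhancer_only"
        loc[in_prom & in_enh] = "Promoter_Enhancer"
        category[peaks.index.get_indexer(grp.index)] = loc
    out["category"] = pd.Categorical(category, categories=CATEGORIES)
    return out


def summarize_categories(classified: pd.DataFrame) -> pd.DataFrame:
    """Per (genotype, mark, category): peak count, cumulative signal and area.

    Area is signalValue x peak width.  Categories with no peaks appear with
    zeros, so every stratum reports all four categories.
    """
    if "category" not in classified.columns:
        raise ValueError("peaks must be classified first")
    df = classified.copy()
    df["width"] = df["end"] - df["start"]
    df["area"] = df["signalValue"] * df["width"]
    grouped = (df.groupby(["genotype", "mark", "category"], observed=False)
               .agg(n_peaks=("signalValue", "size"),
                    cum_signal=("signalValue", "sum"),
                    cum_area=("area", "sum")))
    return grouped.fillna(0.0).reset_index()


def annotate_six_features(peaks: pd.DataFrame, gene_models: pd.DataFrame,
                          tss: pd.DataFrame, promoter_halfwidth: int = 1000,
                          tts_halfwidth: int = 200,
                          precedence: tuple[str, ...] = SIX_FEATURES) -> pd.DataFrame:
    """Assign each peak one genomic feature by the location of its midpoint.

    Precedence (first match wins): promoter-TSS > TTS > Exon (UTR) > CDS >
    intron > intergenic.  Returns the peaks with a ``feature`` column; use
    :func:`feature_percentages` for the per-stratum percentage table.
    """
    required = {"gene_id", "chrom", "strand", "feature", "start", "end"}
    if not required.issubset(gene_models.columns):
        raise ValueError(f"gene models need columns {sorted(required)}")
    bad = gene_models[gene_models["end"] <= gene_models["start"]]
    if len(bad):
        raise ValueError("malformed gene model: empty or inverted intervals")

    prom = _by_chrom(promoter_windows(tss, promoter_halfwidth))
    tts_rows = gene_models[gene_models["feature"] == "TTS"].copy()
    tts_rows["start"] = np.maximum(0, tts_rows["start"] - tts_halfwidth)
    tts_rows["end"] = tts_rows["end"] + tts_halfwidth
    feature_sets = {
        "promoter-TSS": prom,
        "TTS": _by_chrom(tts_rows),
        "Exon (UTR)": _by_chrom(gene_models[gene_models["feature"] == "UTR_exon"]),
        "CDS": _by_chrom(gene_models[gene_models["feature"] == "CDS"]),
        "intron": _by_chrom(gene_models[gene_models["feature"] == "intron"]),
    }

    out = peaks.copy()
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    label = np.full(len(peaks), "intergenic", dtype=object)
    for chrom, grp in peaks.groupby("chrom"):
        pos = peaks.index.get_indexer(grp.index)
        m = mid[pos]
        assigned = np.zeros(len(pos), dtype=bool)
        for feat in precedence:
            if feat == "intergenic":
                continue
            hit = overlaps_any(m, m + 1, *feature_sets[feat].get(chrom, ((), ())))
            label[pos[hit & ~assigned]] = feat
            assigned |= hit
    out["feature"] = pd.Categorical(label, categories=list(precedence))
    return out


def feature_percentages(annotated: pd.DataFrame) -> pd.DataFrame:
    """Percentage of peaks per feature within each (genotype, mark); sums to 100."""
    counts = (annotated.groupby(["genotype", "mark", "feature"], observed=False)
              .size().rename("n").reset_index())
    totals = counts.groupby(["genotype", "mark"])["n"].transform("sum")
    counts["percent"] = np.where(totals > 0, 100.0 * counts["n"] / totals, 0.0)
    return counts
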