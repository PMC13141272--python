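"""Transcriptome-level summaries over differential-expression result tables.

Consumes DESeq2-style per-gene tables (gene_id, chrom, baseMean, baseMeanA,
baseMeanB, log2FoldChange, padj, optional per-replicate Cook's distances) and
implements the study's bespoke downstream statistics:

* DEG calling at |fold change| > 2, padj < 0.05, expression floor 50 in
  wild type and/or mutant.
* Net Transcriptome Change Percent — a baseMean-weighted directional summary
  of the misregulated transcriptome: 100 x sum(baseMean * log2FC) /
  sum(baseMean) over DEG.  Negative means the transcriptome lost more
  highly-expressed output than it gained.
* Wild-type-baseline rank tests (Mann-Whitney on log2 baseMeanA) between
  DEG categories.
* Per-chromosome DEG enrichment with a dual flag rule: FDR <= 0.01 and at
  least 20% deviation from expectation (|log2 obs/exp| >= log2 1.2).
* Venn overlap counts with hypergeometric significance, restored-gene sets
  between single and double mutants, Cook's-distance sensitivity counts,
  and delta-delta-Ct qPCR quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .genome import GenomeModel
from .stats import MannWhitneyResult, mann_whitney

REQUIRED_COLUMNS = ["gene_id", "chrom", "baseMean", "baseMeanA", "baseMeanB",
                    "log2FoldChange", "padj"]


@dataclass
class DEGCall:
    """Up/down/unchanged partition of the expression-filtered gene universe."""

    calls: pd.Series                      # index gene_id -> category
    thresholds: dict = field(default_factory=dict)

    @property
    def universe(self) -> pd.Index:
        return self.calls.index

    def genes(self, category: str) -> pd.Index:
        return self.calls.index[self.calls == category]

    @property
    def deg(self) -> pd.Index:
        return self.calls.index[self.calls.isin(["up", "down"])]

    def counts(self) -> dict[str, int]:
        return {c: int((self.calls == c).sum()) for c in ("up", "down", "unchanged")}


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns {missing}")


def call_deg(table: pd.DataFrame, lfc_abs_min: float = 1.0, padj_max: float = 0.05,
             count_cutoff: float = 50.0) -> DEGCall:
    """Call DEG at the study thresholds (strict inequalities).

    Universe: genes detected at ``count_cutoff`` in wild type and/or mutant
    (baseMeanA >= cutoff OR baseMeanB >= cutoff).  Up: log2FC > lfc_abs_min
    and padj < padj_max; down: the mirror; everything else (including genes
    with missing padj) unchanged.
    """
    _check_table(table)
    if len(table) == 0:
        raise ValueError("empty DEG table")
    in_universe = (table["baseMeanA"] >= count_cutoff) | (table["baseMeanB"] >= count_cutoff)
    uni = table.loc[in_universe]
    if len(uni) == 0:
        warnings.warn("no genes pass the expression cutoff: empty universe")
    sig = uni["padj"].notna() & (uni["padj"] < padj_max)
    cat = np.where(sig & (uni["log2FoldChange"] > lfc_abs_min), "up",
                   np.where(sig & (uni["log2FoldChange"] < -lfc_abs_min), "down",
                            "unchanged"))
    calls = pd.Series(cat, index=pd.Index(uni["gene_id"], name="gene_id"))
    return DEGCall(calls=calls, thresholds={"lfc_abs_min": lfc_abs_min,
                                            "padj_max": padj_max,
                                            "count_cutoff": count_cutoff})


def net_transcriptome_change(call: DEGCall, table: pd.DataFrame) -> float:
    """Net Transcriptome Change Percent over the DEG set.

    100 x sum(baseMean * log2FC) / sum(baseMean), a baseMean-weighted mean of
    DEG log2 fold changes expressed in percent (not bounded by +/-100).
    """
    _check_table(table)
    deg = table.set_index("gene_id").loc[call.deg]
    if len(deg) == 0:
        raise ValueError("net transcriptome change undefined: no DEG")
    weights = deg["baseMean"]
    return float(100.0 * (weights * deg["log2FoldChange"]).sum() / weights.sum())


def baseline_stratified_test(call: DEGCall, table: pd.DataFrame,
                             pseudocount: float = 1.0) -> pd.DataFrame:
    """Mann-Whitney tests on log2 wild-type expression between DEG categories.

    Compares log2(baseMeanA + pseudocount) for down vs up, down vs unchanged
    and up vs unchanged.
    """
    _check_table(table)
    indexed = table.set_index("gene_id")
    values = {}
    for cat in ("down", "up", "unchanged"):
        genes = call.genes(cat)
        if len(genes) == 0:
            raise ValueError(f"category {cat!r} is empty")
        values[cat] = np.log2(indexed.loc[genes, "baseMeanA"].to_numpy() + pseudocount)
    rows = []
    for a, b in (("down", "up"), ("down", "unchanged"), ("up", "unchanged")):
        res: MannWhitneyResult = mann_whitney(values[a], values[b])
        rows.append({"contrast": f"{a}_vs_{b}", "n1": res.n1, "n2": res.n2,
                     "U": res.u, "p": res.p, "method": res.method})
    return pd.DataFrame(rows)


def chromosome_enrichment(call: DEGCall, table: pd.DataFrame, genome: GenomeModel,
                          direction: str, fdr_max: float = 0.01,
                          fold_threshold: float = 1.2) -> pd.DataFrame:
    """Per-chromosome DEG over/under-representation for one direction.

    Observed = DEG of ``direction`` on the chromosome; expected = the DEG
    count scaled by the chromosome's share of the filtered universe.  Wilson
    95% CIs of the observed proportion are mapped to the log2(obs/exp)
    scale; two-sided binomial p-values are FDR-corrected (BH) across
    chromosomes, and a chromosome is flagged when FDR <= ``fdr_max`` AND
    |log2(obs/exp)| >= log2(``fold_threshold``).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    _check_table(table)
    chrom_of = table.set_index("gene_id")["chrom"]
    bad = sorted(set(chrom_of.loc[call.universe]) - set(genome.names))
    if bad:
        raise ValueError(f"universe genes on chromosomes outside the genome: {bad}")

    uni_counts = chrom_of.loc[call.universe].value_counts()
    deg_genes = call.genes(direction)
    n_deg = len(deg_genes)
    if n_deg == 0:
        raise ValueError(f"no {direction}-regulated genes")
    deg_counts = chrom_of.loc[deg_genes].value_counts()

    rows = []
    for name in genome.names:
        n_uni = int(uni_counts.get(name, 0))
        if n_uni == 0:
            warnings.warn(f"chromosome {name} has no universe genes; excluded")
            continue
        share = n_uni / len(call.universe)
        obs = int(deg_counts.get(name, 0))
        expected = n_deg * share
        with np.errstate(divide="ignore"):
            log2_oe = np.log2((obs / n_deg) / share) if obs else -np.inf
        lo, hi = proportion_confint(obs, n_deg, alpha=0.05, method="wilson")
        with np.errstate(divide="ignore"):
            ci_low = np.log2(lo / share) if lo > 0 else -np.inf
            ci_high = np.log2(hi / share)
        p = sps.binomtest(obs, n_deg, share).pvalue
        rows.append({"chrom": name, "direction": direction, "observed": obs,
                     "expected": expected, "log2_obs_exp": log2_oe,
                     "ci_low": ci_low, "ci_high": ci_high, "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["flagged"] = (out["fdr"] <= fdr_max) & \
        (np.abs(out["log2_obs_exp"]) >= np.log2(fold_threshold))
    return out


def harmonize_universe(calls: dict[str, DEGCall]) -> dict[str, DEGCall]:
    """Restrict several DEG calls to their common gene universe.

    Per-contrast expression filters can admit slightly different gene sets
    (the mutant-side mean differs between contrasts); set comparisons
    require one shared universe, so calls are intersected first.
    """
    shared = None
    for call in calls.values():
        shared = set(call.universe) if shared is None else shared & set(call.universe)
    out = {}
    for name, call in calls.items():
        keep = call.calls.index.isin(shared)
        out[name] = DEGCall(calls=call.calls[keep], thresholds=dict(call.thresholds))
    return out


def overlap_sets(calls: dict[str, DEGCall], category: str = "deg") -> pd.DataFrame:
    """Pairwise and triple overlap of DEG sets with hypergeometric significance.

    ``category`` selects which genes form each set: 'deg' (up or down),
    'up' or 'down'.  All calls must share the same universe.  Pairwise
    significance is the upper-tail hypergeometric probability of an overlap
    at least as large, on the shared universe.
    """
    if len(calls) < 2:
        raise ValueError("need at least two DEG calls")
    names = list(calls)
    universe = set(calls[names[0]].universe)
    for name in names[1:]:
        if set(calls[name].universe) != universe:
            raise ValueError(f"universe of {name!r} differs from {names[0]!r}")
    n_universe = len(universe)

    def members(call: DEGCall) -> set[str]:
        return set(call.deg) if category == "deg" else set(call.genes(category))

    sets = {name: members(c) for name, c in calls.items()}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            k = len(sets[a] & sets[b])
            p = float(sps.hypergeom.sf(k - 1, n_universe, len(sets[a]), len(sets[b])))
            rows.append({"sets": f"{a}&{b}", "size_a": len(sets[a]),
                         "size_b": len(sets[b]), "overlap": k, "p": p})
    if len(names) >= 3:
        inter = set.intersection(*sets.values())
        rows.append({"sets": "&".join(names), "size_a": np.nan, "size_b": np.nan,
                     "overlap": len(inter), "p": np.nan})
    return pd.DataFrame(rows)


def restored_genes(single_call: DEGCall, double_call: DEGCall
                   ) -> tuple[pd.Index, float]:
    """Genes DEG in the single mutant but unchanged in the double mutant.

    Returns the restored set and its fraction of the single mutant's DEG.
    """
    if set(single_call.universe) != set(double_call.universe):
        raise ValueError("calls must share the same universe")
    single_deg = single_call.deg
    unchanged_double = set(double_call.genes("unchanged"))
    restored = pd.Index([g for g in single_deg if g in unchanged_double])
    fraction = len(restored) / len(single_deg) if len(single_deg) else 0.0
    return restored, fraction


def cooks_sensitivity(table: pd.DataFrame, replicate: str,
                      cooks_min: float = 1.0,
                      standard: tuple[float, float] = (1.0, 0.05),
                      relaxed: tuple[float, float] = (0.75, 0.1),
                      basemean_min: float = 50.0) -> dict[str, int]:
    """Counts of replicate-influenced genes meeting DE criteria.

    Applies the study's expression filter (baseMean > ``basemean_min`` in
    BOTH conditions), selects genes whose Cook's distance for ``replicate``
    exceeds ``cooks_min``, and counts how many meet the standard
    (|log2FC| > 1, padj < 0.05) and relaxed (|log2FC| > 0.75, padj < 0.1)
    differential-expression criteria.
    """
    _check_table(table)
    col = f"cooks_{replicate}"
    if col not in table.columns:
        raise ValueError(f"no Cook's distance column for replicate {replicate!r}")
    expressed = table[(table["baseMeanA"] > basemean_min)
                      & (table["baseMeanB"] > basemean_min)]
    sensitive = expressed[expressed[col] > cooks_min]

    def meets(df: pd.DataFrame, lfc_min: float, padj_max: float) -> int:
        ok = df["padj"].notna() & (df["padj"] < padj_max) \
            & (df["log2FoldChange"].abs() > lfc_min)
        return int(ok.sum())

    return {"n_sensitive": len(sensitive),
            "n_standard": meets(sensitive, *standard),
            "n_relaxed": meets(sensitive, *relaxed)}


def ddct(ct_table: pd.DataFrame, reference_gene: str = "act-1",
         control_condition: str = "wt") -> pd.DataFrame:
    """Relative qPCR quantification by the delta-delta-Ct method.

    ``ct_table`` holds one row per (gene, condition, replicate) Ct
    measurement.  Per condition, delta-Ct = mean Ct(target) - mean
    Ct(reference); delta-delta-Ct subtracts the control condition's
    delta-Ct, and fold change = 2 ** -ddCt.  Replicate SEMs are propagated
    in quadrature and reported as a fold-change interval.
    """
    for colname in ("gene", "condition", "ct"):
        if colname not in ct_table.columns:
            raise ValueError(f"Ct table missing column {colname!r}")
    grouped = ct_table.groupby(["gene", "condition"])["ct"]
    mean_ct = grouped.mean()
    sem_ct = grouped.sem().fillna(0.0)

    conditions = ct_table["condition"].unique()
    for cond in conditions:
        if (reference_gene, cond) not in mean_ct.index:
            raise ValueError(f"reference gene {reference_gene!r} missing for "
                             f"condition {cond!r}")
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not in table")

    rows = []
    genes = [g for g in ct_table["gene"].unique() if g != reference_gene]
    for gene in genes:
        d_ctrl = mean_ct[(gene, control_condition)] - mean_ct[(reference_gene, control_condition)]
        s_ctrl = np.hypot(sem_ct[(gene, control_condition)],
                          sem_ct[(reference_gene, control_condition)])
        for cond in conditions:
            if cond == control_condition or (gene, cond) not in mean_ct.index:
                continue
            d_cond = mean_ct[(gene, cond)] - mean_ct[(reference_gene, cond)]
            s_cond = np.hypot(sem_ct[(gene, cond)], sem_ct[(reference_gene, cond)])
            dd = d_cond - d_ctrl
            sem_dd = float(np.hypot(s_cond, s_ctrl))
            rows.append({"gene": gene, "condition": cond,
                         "ddct": float(dd), "fold": float(2.0 ** -dd),
                         "sem_ddct": sem_dd,
                         "fold_low": float(2.0 ** -(dd + sem_dd)),
                         "fold_high": float(2.0 ** -(dd - sem_dd))})
    return pd.DataFrame(rows)
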