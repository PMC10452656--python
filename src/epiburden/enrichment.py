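"""Over-representation analysis with occurrence filtering and intersection.

Significant genes from one association stratum are tested against GMT gene
sets with the one-sided hypergeometric upper-tail test, conditioning on the
universe of genes actually tested in the stratum.  To report stability of
each pathway rather than a single p-value, the analysis is repeated over
seeded random subsamples of the significant gene list; per pathway the
lowest and highest BH-adjusted p over iterations and the fraction of
iterations reaching significance (the occurrence) are reported, and
pathways below an occurrence threshold (default 0.9) are filtered out.
Member genes are reported split by the sign of their group coefficient
(increased vs decreased burden in the positive group).

Pathway tables from several datasets are intersected on the set ID to find
pathways recurrently implicated across cohorts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "set_id", "name", "pathway_beta", "genes_increased", "genes_decreased",
    "lowest_p", "highest_p", "occurrence",
]


def read_gmt(path) -> pd.DataFrame:
    """Read a GMT file: set ID, description, then member genes, tab-separated."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            members = list(dict.fromkeys(g for g in parts[2:] if g))
            if not members:
                continue
            rows.append({"set_id": parts[0], "name": parts[1], "genes": members})
    return pd.DataFrame(rows, columns=["set_id", "name", "genes"])


def write_gmt(sets: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in sets.iterrows():
            fh.write("\t".join([row["set_id"], row["name"], *row["genes"]]) + "\n")


def select_genes(results: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Genes significant at BH q < threshold, carrying their coefficient sign."""
    if results.empty:
        log.warning("empty association results; nothing to select")
        return pd.DataFrame(columns=["gene", "beta_group", "q"])
    sel = results[results["q"] < q_threshold][["gene", "beta_group", "q"]]
    return sel.reset_index(drop=True)


def ora_hypergeometric(
    selected: list, universe: list, sets: pd.DataFrame
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation p per gene set, BH-adjusted.

    With N = |universe|, K = |set ∩ universe|, n = |selected| and k the
    observed overlap, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    ``selected`` must be a subset of ``universe``; sets are intersected
    with the universe before testing.
    """
    uni = set(universe)
    sel = set(selected)
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(uni), len(sel)
    rows = []
    for _, row in sets.iterrows():
        members = set(row["genes"]) & uni
        K = len(members)
        k = len(members & sel)
        # upper tail including k: sf(k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_id": row["set_id"], "name": row["name"],
                     "overlap": k, "set_size": K, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set_id", "name", "overlap", "set_size", "p"])
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adjusted"] = []
    return out


def iterate_enrichment(
    selected: pd.DataFrame,
    universe: list,
    sets: pd.DataFrame,
    n_iter: int = 10,
    subsample_fraction: float = 0.9,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated ORA over random subsamples of the significant gene list.

    ``selected`` carries columns ``gene`` and ``beta_group``.  Each
    iteration draws ``subsample_fraction`` of the selected genes without
    replacement (at least one) and reruns the hypergeometric ORA; per set
    the occurrence is the fraction of iterations with adjusted p < alpha.
    A per-gene auxiliary column reports, for each member gene, the fraction
    of iterations in which the set was significant with that gene in the
    subsampled overlap.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = selected["gene"].tolist()
    betas = dict(zip(selected["gene"], selected["beta_group"]))
    take = max(1, round(subsample_fraction * len(genes))) if genes else 0

    low: dict[str, float] = {}
    high: dict[str, float] = {}
    hits: dict[str, int] = {}
    gene_hits: dict[str, dict[str, int]] = {}
    for _ in range(n_iter):
        sub = list(rng.choice(genes, size=take, replace=False)) if take else []
        ora = ora_hypergeometric(sub, universe, sets)
        for _, row in ora.iterrows():
            sid = row["set_id"]
            padj = row["p_adjusted"]
            low[sid] = min(low.get(sid, np.inf), padj)
            high[sid] = max(high.get(sid, -np.inf), padj)
            if padj < alpha:
                hits[sid] = hits.get(sid, 0) + 1
                members = set(sets.loc[sets["set_id"] == sid, "genes"].iloc[0])
                for g in members & set(sub):
                    gene_hits.setdefault(sid, {})[g] = gene_hits.setdefault(sid, {}).get(g, 0) + 1

    rows = []
    for _, srow in sets.iterrows():
        sid = srow["set_id"]
        members = set(srow["genes"])
        inc = sorted(g for g in members if g in betas and betas[g] > 0)
        dec = sorted(g for g in members if g in betas and betas[g] < 0)
        sig_betas = [betas[g] for g in inc + dec]
        gh = gene_hits.get(sid, {})
        rows.append(
            {
                "set_id": sid,
                "name": srow["name"],
                "pathway_beta": float(np.mean(sig_betas)) if sig_betas else np.nan,
                "genes_increased": ";".join(inc),
                "genes_decreased": ";".join(dec),
                "lowest_p": low.get(sid, np.nan),
                "highest_p": high.get(sid, np.nan),
                "occurrence": hits.get(sid, 0) / n_iter,
                "gene_occurrence": ";".join(
                    f"{g}={gh[g] / n_iter:.2f}" for g in sorted(gh)
                ),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["iteration_scheme"] = (
        "seeded subsampling of the significant gene list "
        f"(fraction={subsample_fraction}, n_iter={n_iter}, alpha={alpha})"
    )
    out.attrs["pathway_beta_rule"] = "mean of significant member genes' group coefficients"
    return out


def filter_by_occurrence(results: pd.DataFrame, min_occurrence: float = 0.9) -> pd.DataFrame:
    """Keep pathways significant in at least ``min_occurrence`` of iterations."""
    return results[results["occurrence"] >= min_occurrence].reset_index(drop=True)


def intersect_pathways(tables: list[pd.DataFrame], names: list[str] | None = None) -> pd.DataFrame:
    """Set IDs present in every table, with per-dataset annotations joined.

    ``tables`` are occurrence-filtered pathway tables, one per dataset.
    The output has one row per shared set ID with each dataset's gene lists
    and p-value range as suffixed columns.
    """
    if len(tables) < 2:
        raise ValueError("intersection needs at least two pathway tables")
    names = names or [f"dataset{i + 1}" for i in range(len(tables))]
    shared = set(tables[0]["set_id"])
    for t in tables[1:]:
        shared &= set(t["set_id"])
    base = tables[0][tables[0]["set_id"].isin(shared)][["set_id", "name"]].copy()
    base = base.sort_values("set_id").reset_index(drop=True)
    for t, label in zip(tables, names):
        sub = t[t["set_id"].isin(shared)].set_index("set_id")
        for col in ("pathway_beta", "genes_increased", "genes_decreased", "lowest_p", "highest_p", "occurrence"):
            base[f"{col}_{label}"] = base["set_id"].map(sub[col])
    return base


def summarize_pathway_beta(result_row: pd.Series, betas: dict) -> float:
    """Mean group coefficient over a pathway's significant member genes."""
    members = [g for g in (result_row["genes_increased"].split(";") + result_row["genes_decreased"].split(";")) if g]
    vals = [betas[g] for g in members if g in betas]
    if not vals:
        return float("nan")
    return float(np.mean(vals))
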