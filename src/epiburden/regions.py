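"""Probe-to-gene-region annotation and WSEMS aggregation.

Probes are annotated in the Illumina manifest dialect: ``UCSC_RefGene_Name``
and ``UCSC_RefGene_Group`` are parallel semicolon-joined lists, paired
positionally.  Only the four gene-region classes TSS1500, TSS200, 1stExon
and Body take part in scoring; other groups (5'UTR, 3'UTR, ...) are
dropped.

The weighted stochastic epimutation score (WSEMS) of a sample for a
(gene, region, direction) cell is the sum of the quartile weights (1-4) of
that sample's epimutation calls on probes annotated to the gene region.  A
probe annotated to several (gene, region) pairs contributes its full weight
to each pair.
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)

REGION_CLASSES = ("TSS1500", "TSS200", "1stExon", "Body")

PROBE_COL = "IlmnID"
CHROM_COL = "CHR"
POS_COL = "MAPINFO"
GENE_COL = "UCSC_RefGene_Name"
GROUP_COL = "UCSC_RefGene_Group"

SCORE_COLUMNS = ["sample", "gene", "region", "direction", "wsems"]


def parse_annotation(
    source,
    probe_col: str = PROBE_COL,
    gene_col: str = GENE_COL,
    group_col: str = GROUP_COL,
) -> pd.DataFrame:
    """Parse manifest-dialect annotation into long (probe, gene, region) pairs.

    ``source`` is a CSV path or an already-loaded DataFrame.  Semicolon
    lists in the gene-name and gene-group columns are split and paired
    positionally; probes whose two lists disagree in length are skipped with
    a warning; pairs are deduplicated per probe; region classes outside the
    four-class vocabulary are dropped.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, dtype=str)
    for col in (probe_col, gene_col, group_col):
        if col not in df.columns:
            raise ValueError(f"annotation is missing mandatory column {col!r}")

    records: list[tuple[str, str, str]] = []
    n_skipped = 0
    for probe, genes, groups in zip(df[probe_col], df[gene_col], df[group_col]):
        if pd.isna(genes) or pd.isna(groups) or genes == "" or groups == "":
            continue
        gene_list = str(genes).split(";")
        group_list = str(groups).split(";")
        if len(gene_list) != len(group_list):
            n_skipped += 1
            continue
        seen = set()
        for gene, region in zip(gene_list, group_list):
            if region not in REGION_CLASSES:
                continue
            if (gene, region) in seen:
                continue
            seen.add((gene, region))
            records.append((probe, gene, region))
    if n_skipped:
        log.warning("%d probes skipped: gene/group list length mismatch", n_skipped)
    return pd.DataFrame(records, columns=["probe", "gene", "region"])


def write_annotation(pairs: pd.DataFrame, extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Serialize long (probe, gene, region) pairs back to the manifest dialect.

    ``extra`` optionally supplies per-probe chromosome/position columns
    (indexed by probe).  Pair order within a probe is preserved.
    """
    grouped = pairs.groupby("probe", sort=True)
    rows = []
    for probe, grp in grouped:
        rows.append(
            {
                PROBE_COL: probe,
                GENE_COL: ";".join(grp["gene"]),
                GROUP_COL: ";".join(grp["region"]),
            }
        )
    out = pd.DataFrame(rows)
    if extra is not None:
        out = out.merge(
            extra.rename_axis("probe_").reset_index().rename(columns={"probe_": PROBE_COL}),
            on=PROBE_COL,
            how="left",
        )
        cols = [PROBE_COL] + [c for c in (CHROM_COL, POS_COL) if c in out.columns]
        cols += [GENE_COL, GROUP_COL]
        out = out[cols]
    return out


def aggregate_wsems(calls: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Sum call weights into WSEMS per (sample, gene, region, direction).

    ``calls`` must carry assigned ranks; ``annotation`` is the long pair
    table from :func:`parse_annotation`.  Probes without annotation
    contribute nothing; zero scores are left implicit (densify with
    :func:`dense_scores` when a full sample x gene grid is needed).
    """
    if calls.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    if calls["rank"].isna().any():
        raise ValueError("calls lack quartile ranks; run rank_deltas first")
    merged = calls.merge(annotation, on="probe", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    scores = (
        merged.groupby(["sample", "gene", "region", "direction"], observed=True)["rank"]
        .sum()
        .rename("wsems")
        .reset_index()
    )
    scores["wsems"] = scores["wsems"].astype(int)
    return scores


def dense_scores(
    scores: pd.DataFrame,
    samples,
    direction: str,
    region: str,
) -> pd.DataFrame:
    """Genes x samples WSEMS grid for one (region, direction) stratum.

    Samples without calls get explicit zeros; genes absent from the stratum
    are absent from the grid (they are untestable downstream).
    """
    sub = scores[(scores["direction"] == direction) & (scores["region"] == region)]
    if sub.empty:
        return pd.DataFrame(columns=pd.Index(samples, name="sample"))
    grid = sub.pivot_table(index="gene", columns="sample", values="wsems", fill_value=0)
    return grid.reindex(columns=pd.Index(samples, name="sample"), fill_value=0).astype(int)
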