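"""Synthetic methylation cohorts with planted stochastic epimutations.

The generator emulates the statistical shape of tumour methylation-array
cohorts: beta values in (0, 1) with bimodal probe baselines (unmethylated /
intermediate / methylated probe classes), a binary group label at roughly
80/20 prevalence, age / stage / epithelial-fraction covariates, and rare
extreme per-sample outliers.  Outliers are planted on the M scale at a
displacement of at least 4 x IQR beyond the relevant quartile of the
probe's baseline distribution, i.e. strictly outside the 3 x IQR calling
fences, so that recovering them is a construction guarantee up to
quartile-estimation noise.  Designated "signal" genes receive an elevated
outlier rate (a multiplicative factor on the base rate) in one group only,
at the probes of one gene region and one direction, creating a
group-differential epimutation burden for the association stage to find.

Every planted call is recorded in a truth table so sensitivity, burden
contrast and false-call rates can be measured against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epimutations import DIRECTIONS, HYPER
from .matrix import BETA_SCALE, MethylationMatrix
from .regions import (
    CHROM_COL,
    GENE_COL,
    GROUP_COL,
    POS_COL,
    PROBE_COL,
    REGION_CLASSES,
)

GROUP_POSITIVE = "positive"
GROUP_NEGATIVE = "negative"
STAGES = ("I", "II", "III", "IV")

# fraction of each gene's probe block assigned to each region class, in
# order TSS1500, TSS200, 1stExon, Body; the layout is deterministic so all
# genes have comparable region sizes
REGION_LAYOUT = ((0.35, "TSS1500"), (0.15, "TSS200"), (0.10, "1stExon"), (1.0, "Body"))


class ConfigurationError(ValueError):
    """Invalid or degenerate simulation configuration."""


@dataclass
class CovariateModel:
    """Distributions for the simulated clinical covariates.

    Age is normal (clipped to [18, 95] years); stage is an ordered
    categorical over I-IV; the epithelial fraction is beta-distributed.
    Defaults mimic a large breast-tumour cohort: mean age ~58 (sd ~13),
    most cases in stages I-II, epithelial fraction centred near 0.7.
    """

    age_mean: float = 57.65
    age_sd: float = 12.74
    stage_probs: tuple = (0.20, 0.55, 0.20, 0.05)
    epithelial_a: float = 14.0
    epithelial_b: float = 6.0

    def __post_init__(self) -> None:
        if len(self.stage_probs) != len(STAGES) or abs(sum(self.stage_probs) - 1) > 1e-9:
            raise ConfigurationError("stage_probs must be 4 probabilities summing to 1")


@dataclass
class SignalGene:
    """A gene region with a group-differential planted epimutation rate."""

    gene: str
    region: str = "TSS1500"
    direction: str = HYPER
    rate_multiplier: float = 8.0
    affected_group: str = GROUP_POSITIVE

    def __post_init__(self) -> None:
        if self.region not in REGION_CLASSES:
            raise ConfigurationError(f"unknown region {self.region!r}")
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.rate_multiplier < 1:
            raise ConfigurationError("rate_multiplier must be >= 1")
        if self.affected_group not in (GROUP_POSITIVE, GROUP_NEGATIVE):
            raise ConfigurationError(f"unknown group {self.affected_group!r}")


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    ``probe_mean_mixture`` lists (weight, (a, b)) components; each probe's
    baseline mean beta is drawn from the beta(a, b) of its class.  Within a
    probe, sample values are beta-distributed around that mean with
    concentration ``within_probe_dispersion``.  ``base_epimutation_rate``
    is the per-(probe, sample) probability of a planted extreme outlier;
    the default reflects the elevated stochastic epimutation burden of
    tumour methylomes rather than healthy tissue.
    """

    n_samples: int = 200
    n_probes: int = 2000
    n_genes: int = 100
    group_prevalence: float = 0.8
    probe_mean_mixture: tuple = (
        (0.45, (2.0, 18.0)),
        (0.10, (5.0, 5.0)),
        (0.45, (18.0, 2.0)),
    )
    within_probe_dispersion: float = 50.0
    base_epimutation_rate: float = 0.02
    signal_genes: tuple = ()
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    multi_gene_fraction: float = 0.10
    outlier_displacement: tuple = (5.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.group_prevalence < 1:
            raise ConfigurationError(
                f"group_prevalence must lie in (0, 1), got {self.group_prevalence}"
            )
        if not 0 <= self.base_epimutation_rate <= 1:
            raise ConfigurationError("base_epimutation_rate must lie in [0, 1]")
        if self.n_probes < self.n_genes:
            raise ConfigurationError("need n_probes >= n_genes")
        if not 0 <= self.multi_gene_fraction <= 1:
            raise ConfigurationError("multi_gene_fraction must lie in [0, 1]")
        if self.outlier_displacement[0] < 4.0:
            raise ConfigurationError("outlier displacement must start at >= 4 x IQR")
        self.signal_genes = tuple(
            s if isinstance(s, SignalGene) else SignalGene(*s) for s in self.signal_genes
        )
        w = sum(w for w, _ in self.probe_mean_mixture)
        if abs(w - 1) > 1e-9:
            raise ConfigurationError("probe_mean_mixture weights must sum to 1")

    # -- identifier helpers ------------------------------------------------
    def sample_ids(self) -> pd.Index:
        return pd.Index([f"S{i:04d}" for i in range(self.n_samples)], name="sample")

    def probe_ids(self) -> pd.Index:
        return pd.Index([f"cg{i:08d}" for i in range(self.n_probes)], name="probe")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(8)[stream])


def with_signal(
    n_signal: int = 10,
    region: str = "TSS1500",
    direction: str = HYPER,
    rate_multiplier: float = 8.0,
    affected_group: str = GROUP_POSITIVE,
    **kwargs,
) -> SimulationConfig:
    """A SimulationConfig whose first ``n_signal`` genes carry planted signal."""
    cfg = SimulationConfig(**kwargs)
    if n_signal > cfg.n_genes:
        raise ConfigurationError("more signal genes than genes")
    sig = tuple(
        SignalGene(g, region, direction, rate_multiplier, affected_group)
        for g in cfg.gene_ids()[:n_signal]
    )
    return SimulationConfig(**{**kwargs, "signal_genes": sig})


@dataclass
class TruthTable:
    """Ground truth of one simulated cohort.

    ``calls`` lists every planted outlier as (sample, probe, direction);
    ``signal_genes`` the designated gene regions with their multipliers.
    """

    calls: pd.DataFrame
    signal_genes: pd.DataFrame

    def planted_set(self) -> set[tuple[str, str, str]]:
        return set(map(tuple, self.calls[["sample", "probe", "direction"]].to_numpy()))


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Sample covariate table: group, age, stage, epithelial per sample."""
    rng = config._rng(0)
    cm = config.covariate_model
    n = config.n_samples
    group = np.where(
        rng.random(n) < config.group_prevalence, GROUP_POSITIVE, GROUP_NEGATIVE
    )
    age = np.clip(rng.normal(cm.age_mean, cm.age_sd, n), 18.0, 95.0).round(1)
    stage = rng.choice(STAGES, size=n, p=cm.stage_probs)
    epithelial = rng.beta(cm.epithelial_a, cm.epithelial_b, n).round(4)
    return pd.DataFrame(
        {"group": group, "age": age, "stage": stage, "epithelial": epithelial},
        index=config.sample_ids(),
    )


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Manifest-dialect annotation table for the simulated probes.

    Probes are assigned to genes in contiguous blocks (every gene gets at
    least one probe) with a fixed within-block region layout, so all genes
    have comparable TSS1500/TSS200/1stExon/Body probe counts.  A fraction
    of probes additionally annotates to the next gene's Body (semicolon
    lists), exercising the multi-gene manifest dialect.  The layout is a
    pure function of the shape parameters — annotation is shared by
    cohorts that differ only in seed.
    """
    probes = config.probe_ids()
    genes = config.gene_ids()
    per_gene = config.n_probes // config.n_genes
    gene_of = np.minimum(np.arange(config.n_probes) // per_gene, config.n_genes - 1)

    rows = []
    for g in range(config.n_genes):
        block = np.flatnonzero(gene_of == g)
        k = block.size
        cut_prev = 0
        regions = []
        for frac, region in REGION_LAYOUT:
            cut = k if frac >= 1.0 else min(k, cut_prev + max(1, round(frac * k)))
            regions += [region] * (cut - cut_prev)
            cut_prev = cut
            if cut_prev >= k:
                break
        for pi, region in zip(block, regions):
            names = [genes[g]]
            groups = [region]
            stride = round(1 / config.multi_gene_fraction) if config.multi_gene_fraction else 0
            if stride and pi % stride == 0 and config.n_genes > 1:
                names.append(genes[(g + 1) % config.n_genes])
                groups.append("Body")
            rows.append(
                {
                    PROBE_COL: probes[pi],
                    CHROM_COL: f"chr{g % 22 + 1}",
                    POS_COL: 1000 + 100 * pi,
                    GENE_COL: ";".join(names),
                    GROUP_COL: ";".join(groups),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["genome_build"] = "hg19"
    return out


def generate_methylation(
    config: SimulationConfig, cohort: pd.DataFrame
) -> tuple[MethylationMatrix, TruthTable]:
    """Beta-value matrix with planted outliers, plus the truth table.

    Baseline betas come from the probe-class mixture; planted outliers are
    positioned on the M scale at ``Q +/- d * IQR`` of the probe's baseline
    distribution with d drawn uniformly from ``config.outlier_displacement``
    (beyond the third quartile for hypermethylated, below the first for
    hypomethylated calls), then transformed back to the beta scale.
    """
    if config.within_probe_dispersion <= 0:
        raise ConfigurationError("within_probe_dispersion must be positive")
    if not cohort.index.equals(config.sample_ids()):
        raise ConfigurationError("cohort does not match config sample IDs")
    rng = config._rng(1)
    n_p, n_s = config.n_probes, config.n_samples

    # baseline: per-probe mean from the mixture, per-cell beta around it
    weights = np.array([w for w, _ in config.probe_mean_mixture])
    comp = rng.choice(len(weights), size=n_p, p=weights)
    shapes = np.array([ab for _, ab in config.probe_mean_mixture])
    mu = rng.beta(shapes[comp, 0], shapes[comp, 1])
    mu = np.clip(mu, 0.01, 0.99)
    conc = config.within_probe_dispersion
    betas = rng.beta(mu[:, None] * conc, (1 - mu[:, None]) * conc, size=(n_p, n_s))
    betas = np.clip(betas, 1e-6, 1 - 1e-6)

    # per-cell planting probability and direction
    rate = np.full((n_p, n_s), float(config.base_epimutation_rate))
    direction = rng.choice(DIRECTIONS, size=(n_p, n_s))
    probe_pos = {p: i for i, p in enumerate(config.probe_ids())}
    sample_pos = {s: i for i, s in enumerate(cohort.index)}
    annotation_pairs = _annotation_pairs(config)
    for sig in config.signal_genes:
        probes = annotation_pairs[
            (annotation_pairs["gene"] == sig.gene) & (annotation_pairs["region"] == sig.region)
        ]["probe"]
        pi = np.array([probe_pos[p] for p in probes])
        si = np.array([sample_pos[s] for s in cohort.index[cohort["group"] == sig.affected_group]])
        if pi.size == 0 or si.size == 0:
            continue
        rate[np.ix_(pi, si)] = np.minimum(1.0, config.base_epimutation_rate * sig.rate_multiplier)
        direction[np.ix_(pi, si)] = sig.direction

    planted = rng.random((n_p, n_s)) < rate

    # place outliers on the M scale beyond the baseline quartiles
    m = np.log2(betas / (1 - betas))
    base = np.where(planted, np.nan, m)
    q1 = np.nanquantile(base, 0.25, axis=1)
    q3 = np.nanquantile(base, 0.75, axis=1)
    # fall back to all-values quartiles for probes planted everywhere
    q1 = np.where(np.isnan(q1), np.quantile(m, 0.25, axis=1), q1)
    q3 = np.where(np.isnan(q3), np.quantile(m, 0.75, axis=1), q3)
    iqr = q3 - q1
    lo, hi = config.outlier_displacement
    disp = rng.uniform(lo, hi, size=(n_p, n_s))
    pi, si = np.nonzero(planted)
    hyper_mask = direction[pi, si] == HYPER
    m_out = np.where(
        hyper_mask,
        q3[pi] + disp[pi, si] * iqr[pi],
        q1[pi] - disp[pi, si] * iqr[pi],
    )
    m[pi, si] = m_out
    from scipy.special import expit

    betas_out = expit(m * np.log(2.0))
    betas_out = np.clip(betas_out, 1e-9, 1 - 1e-9)

    matrix = MethylationMatrix(
        pd.DataFrame(betas_out, index=config.probe_ids(), columns=cohort.index),
        scale=BETA_SCALE,
        meta={"simulated": True, "seed": config.seed},
    )
    calls = pd.DataFrame(
        {
            "sample": cohort.index[si],
            "probe": config.probe_ids()[pi],
            "direction": direction[pi, si],
        }
    )
    signal_df = pd.DataFrame(
        [
            {
                "gene": s.gene,
                "region": s.region,
                "direction": s.direction,
                "rate_multiplier": s.rate_multiplier,
                "affected_group": s.affected_group,
            }
            for s in config.signal_genes
        ],
        columns=["gene", "region", "direction", "rate_multiplier", "affected_group"],
    )
    return matrix, TruthTable(calls=calls, signal_genes=signal_df)


def _annotation_pairs(config: SimulationConfig) -> pd.DataFrame:
    from .regions import parse_annotation

    return parse_annotation(generate_annotation(config))


def generate_genesets(
    config: SimulationConfig, n_sets: int = 20, set_size: int = 15
) -> pd.DataFrame:
    """GMT-style gene-set collection over the simulated gene universe.

    The first set is the designated signal pathway: it contains every
    signal gene (up to ``set_size``) padded with random non-signal genes,
    so enrichment recovery is testable against ground truth.  Remaining
    sets are uniform draws from the gene universe.
    """
    if set_size > config.n_genes:
        raise ConfigurationError("set_size exceeds the number of genes")
    if n_sets < 1:
        raise ConfigurationError("need at least one set")
    rng = config._rng(2)
    genes = np.array(config.gene_ids())
    signal = [s.gene for s in config.signal_genes]
    rows = []

    members = list(dict.fromkeys(signal))[:set_size]
    fill = [g for g in genes if g not in members]
    pad = rng.choice(fill, size=set_size - len(members), replace=False)
    rows.append(
        {
            "set_id": "PW0000",
            "name": "planted signal pathway",
            "genes": sorted(members + list(pad)),
        }
    )
    for i in range(1, n_sets):
        rows.append(
            {
                "set_id": f"PW{i:04d}",
                "name": f"random pathway {i}",
                "genes": sorted(rng.choice(genes, size=set_size, replace=False)),
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> dict:
    """Generate all artefacts of one cohort (convenience bundle)."""
    cohort = generate_cohort(config)
    matrix, truth = generate_methylation(config, cohort)
    return {
        "config": config,
        "cohort": cohort,
        "matrix": matrix,
        "truth": truth,
        "annotation": generate_annotation(config),
    }
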