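"""Q-length-correlated expression-trend analysis.

Given a gene x sample abundance matrix from genotypes carrying 0, 2, 4 or 7
glutamines (several replicates each), the stage selects genes whose
expression responds monotonically to polyQ length:

1. library-size normalization to counts per million (CPM);
2. base-mean floor — genes averaging below 1 CPM are dropped;
3. stepwise filter — genotype means must be strictly increasing
   (0Q < 2Q < 4Q < 7Q) or strictly decreasing across the ordered genotypes;
4. Spearman correlation of replicate-level abundance against Q length,
   two-sided; a gene passes when it is stepwise-monotone and its
   correlation p-value is below alpha.

Companion utilities: population-sd z-scaling of expression rows for
heatmaps, top-k Jaccard overlap of ranked differentially-expressed gene
lists, and the signed gene-ontology z-score
``(n_up - n_down) / sqrt(n_up + n_down)``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization: value * 1e6 / column sum."""
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {', '.join(map(str, zero.index))}")
    return counts * 1e6 / sums


def base_mean_filter(cpm: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Retain genes whose mean CPM across all samples is >= ``threshold``."""
    return cpm.loc[cpm.mean(axis=1) >= threshold]


def _genotype_order(q_by_sample: pd.Series) -> list:
    return sorted(q_by_sample.unique())


def stepwise_monotone(cpm: pd.DataFrame, q_by_sample: pd.Series,
                      expected_genotypes: tuple | None = None) -> pd.Series:
    """Per-gene direction of genotype-mean expression across ordered Q.

    ``up`` when genotype means strictly increase with Q, ``down`` when they
    strictly decrease, ``none`` otherwise; ties fail strictness. When
    ``expected_genotypes`` is given, every one of them must have at least
    one sample.
    """
    q_by_sample = q_by_sample.loc[cpm.columns]
    qs = _genotype_order(q_by_sample)
    if expected_genotypes is not None:
        absent = sorted(set(expected_genotypes) - set(qs))
        if absent:
            raise ValueError(f"genotype(s) without samples: {absent}")
    if len(qs) < 2:
        raise ValueError("need at least two genotypes")
    means = pd.concat(
        {q: cpm.loc[:, q_by_sample[q_by_sample == q].index].mean(axis=1) for q in qs},
        axis=1,
    )
    if means.isna().any().any():
        missing = [q for q in qs if means[q].isna().all()]
        raise ValueError(f"genotype(s) without samples: {missing}")
    diffs = means.diff(axis=1).iloc[:, 1:]
    up = (diffs > 0).all(axis=1)
    down = (diffs < 0).all(axis=1)
    out = pd.Series("none", index=cpm.index, name="direction")
    out[up] = "up"
    out[down] = "down"
    return out


def q_correlation(cpm: pd.DataFrame, q_by_sample: pd.Series,
                  alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
    """Spearman correlation of replicate-level abundance with Q length.

    Q is the ordinal covariate (ties handled by midranks). ``passes``
    requires a non-``none`` stepwise direction and p below ``alpha``;
    ``bh=True`` applies Benjamini–Hochberg correction to the p-values before
    thresholding (off by default). Constant genes get an undefined rho and
    never pass.
    """
    q_by_sample = q_by_sample.loc[cpm.columns]
    direction = stepwise_monotone(cpm, q_by_sample)
    q = q_by_sample.to_numpy(dtype=float)
    rhos = np.full(len(cpm), np.nan)
    pvals = np.full(len(cpm), np.nan)
    values = cpm.to_numpy(dtype=float)
    for i in range(len(cpm)):
        row = values[i]
        if np.ptp(row) == 0:
            continue
        rho, p = stats.spearmanr(row, q)
        rhos[i], pvals[i] = rho, p
    p_test = pvals.copy()
    if bh:
        mask = ~np.isnan(pvals)
        p_test[mask] = stats.false_discovery_control(pvals[mask], method="bh")
    passes = (direction.to_numpy() != "none") & (p_test < alpha)
    return pd.DataFrame(
        {
            "gene": cpm.index,
            "direction": direction.to_numpy(),
            "rho": rhos,
            "p": pvals,
            "p_adj" if bh else "p_test": p_test,
            "passes": passes,
        }
    ).set_index("gene")


def gene_zscore_scale(m: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Row-wise z-scaling with the population (n denominator) sd.

    Each scaled row has mean 0 and population sd 1. Constant rows cannot be
    scaled; they are returned as NaN and their index is reported separately.
    """
    mean = m.mean(axis=1)
    sd = m.std(axis=1, ddof=0)
    flagged = m.index[sd == 0]
    scaled = m.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    return scaled, flagged


def jaccard_topk(list_a, list_b, k: int = 100) -> float:
    """Jaccard similarity of the top-k entries of two ranked gene lists."""
    list_a, list_b = list(list_a), list(list_b)
    for name, lst in (("first", list_a), ("second", list_b)):
        if len(set(lst)) != len(lst):
            raise ValueError(f"duplicate entries in the {name} list")
        if len(lst) < k:
            logger.info("%s list has %d (< k=%d) entries; using all", name, len(lst), k)
    top_a, top_b = set(list_a[:k]), set(list_b[:k])
    union = top_a | top_b
    return len(top_a & top_b) / len(union)


def go_zscore(n_up: int, n_down: int) -> float:
    """Signed enrichment score ``(n_up - n_down) / sqrt(n_up + n_down)``."""
    total = n_up + n_down
    if total <= 0:
        raise ValueError("n_up + n_down must be positive")
    return (n_up - n_down) / math.sqrt(total)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class QTrendModel:
    """Monotone Q-length expression-trend analysis.

    Parameters
    ----------
    counts : gene x sample abundance matrix (raw counts unless
        ``is_cpm=True``).
    sample_meta : either a mapping/Series sample -> Q length, or a DataFrame
        with columns ``sample`` and ``Q`` (optionally ``replicate``).
    is_cpm : set True when ``counts`` is already CPM-normalized.
    """

    def __init__(self, counts: pd.DataFrame, sample_meta, is_cpm: bool = False):
        if isinstance(sample_meta, pd.DataFrame):
            q = sample_meta.set_index("sample")["Q"]
        else:
            q = pd.Series(dict(sample_meta), name="Q")
        missing = [s for s in counts.columns if s not in q.index]
        if missing:
            raise ValueError(f"samples without a Q label: {missing}")
        self.counts = counts
        self.q_by_sample = q.loc[counts.columns]
        self.is_cpm = is_cpm
        reps = self.q_by_sample.value_counts()
        if (reps < 2).any():
            logger.warning(
                "genotype(s) with a single replicate: %s",
                ", ".join(str(g) for g in reps[reps < 2].index),
            )

    @classmethod
    def from_files(cls, counts_path, meta_path, **kw) -> "QTrendModel":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(counts, meta, **kw)

    def fit(self, alpha: float = 0.05, cpm_threshold: float = 1.0,
            bh: bool = False) -> "QTrendResults":
        cpm = self.counts if self.is_cpm else cpm_normalize(self.counts)
        cpm = base_mean_filter(cpm, threshold=cpm_threshold)
        trend = q_correlation(cpm, self.q_by_sample, alpha=alpha, bh=bh)
        return QTrendResults(self, cpm, trend, alpha)


class QTrendResults:
    """Fitted expression-trend analysis.

    Attributes
    ----------
    cpm : the filtered CPM matrix the statistics were computed on.
    trend : per-gene direction, Spearman rho/p and pass flag.
    """

    def __init__(self, model, cpm, trend, alpha):
        self.model = model
        self.cpm = cpm
        self.trend = trend
        self.alpha = alpha

    @property
    def n_stepwise(self) -> int:
        return int((self.trend["direction"] != "none").sum())

    @property
    def n_passing(self) -> int:
        return int(self.trend["passes"].sum())

    @property
    def passing_genes(self) -> list[str]:
        return list(self.trend.index[self.trend["passes"]])

    def scaled(self, passing_only: bool = True) -> pd.DataFrame:
        """Z-scaled expression rows (population sd), for heatmap display."""
        m = self.cpm.loc[self.passing_genes] if passing_only else self.cpm
        scaled, _ = gene_zscore_scale(m)
        return scaled

    def summary(self) -> str:
        return "\n".join(
            [
                "Q-length expression-trend analysis",
                f"  genes after CPM floor: {len(self.cpm)}    "
                f"samples: {self.cpm.shape[1]}    alpha: {self.alpha}",
                f"  stepwise monotone genes (strict across ordered Q): "
                f"{self.n_stepwise}",
                f"  significantly Q-correlated among them: {self.n_passing}",
            ]
        )
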