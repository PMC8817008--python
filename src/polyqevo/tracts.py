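"""PolyQ tract detection, cross-ortholog statistics and outlier ranking.

A polyQ tract is a run of at least ``min_len`` consecutive glutamine codons
(exactly CAA or CAG) in a coding sequence. For each tract three metrics are
computed:

* ``LQ``  — length of the longest pure Q stretch (codon count);
* ``LNI`` — length of the longest non-interrupted CAG run within it;
* ``PQ``  — tract purity, the proportion of CAG among its Q codons.

A focal (typically human) tract is compared against its ortholog set through
z-scores, ``z_m = (focal_m - mean(ortholog_m)) / sd(ortholog_m)`` with the
sample (n-1) standard deviation and the focal value excluded from the
reference set. Ortholog tracts are located through the alignment window
spanned by the focal tract, extended across gap blocks conjoined to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polyqevo._codons import GAP_CODON, Q_CODONS, STOP_CODONS, split_codons
from polyqevo.seqio import CodonAlignment, Sequence


@dataclass(frozen=True)
class Tract:
    """One polyQ tract: contiguous Q codons in an ungapped CDS.

    ``start_codon``/``end_codon`` are 0-based half-open codon indices.
    """

    gene: str
    taxon: str
    start_codon: int
    end_codon: int
    codons: tuple[str, ...]

    def __post_init__(self):
        if len(self.codons) < 1 or self.end_codon - self.start_codon != len(self.codons):
            raise ValueError("tract indices inconsistent with codon count")
        bad = [c for c in self.codons if c not in Q_CODONS]
        if bad:
            raise ValueError(f"non-Q codon in tract: {bad[0]}")

    def __len__(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class TractRecord:
    """LQ / LNI / PQ metrics of one tract."""

    LQ: int
    LNI: int
    PQ: float


@dataclass(frozen=True)
class TractZScores:
    """Standardized scores of a focal tract against its ortholog set.

    A metric's z is None (undefined) when the ortholog standard deviation
    is zero.
    """

    z_LQ: float | None
    z_LNI: float | None
    z_PQ: float | None
    n_orthologs: int


def find_polyq_tracts(cds: Sequence | str, min_len: int = 4,
                      gene: str = "", taxon: str = "") -> list[Tract]:
    """Maximal runs of >= ``min_len`` consecutive Q codons, in 5'->3' order.

    A terminal stop codon is trimmed; an internal stop is an error. Any codon
    outside {CAA, CAG} — including ambiguous codons such as CAR or CAN —
    breaks a run and is never counted as Q.
    """
    if isinstance(cds, Sequence):
        gene = gene or cds.id
        taxon = taxon or cds.id
        cds = cds.seq
    codons = split_codons(cds.upper().replace("-", ""))
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon position {i + 1}")
    tracts: list[Tract] = []
    i = 0
    n = len(codons)
    while i < n:
        if codons[i] in Q_CODONS:
            j = i
            while j < n and codons[j] in Q_CODONS:
                j += 1
            if j - i >= min_len:
                tracts.append(Tract(gene, taxon, i, j, tuple(codons[i:j])))
            i = j
        else:
            i += 1
    return tracts


def tract_metrics(t: Tract) -> TractRecord:
    """LQ, LNI and PQ for one tract.

    LNI counts only CAG codons, so an all-CAA tract has LNI = 0.
    """
    lq = len(t.codons)
    lni = best = 0
    for c in t.codons:
        best = best + 1 if c == "CAG" else 0
        lni = max(lni, best)
    n_cag = sum(1 for c in t.codons if c == "CAG")
    return TractRecord(LQ=lq, LNI=lni, PQ=n_cag / lq)


def map_tract_window(aln: CodonAlignment, focal_taxon: str, focal_tract: Tract
                     ) -> tuple[int, int]:
    """Alignment-column window (0-based half-open) of the focal tract.

    The window is the span of columns holding the tract's codons, extended
    through any maximal gap-column block in the focal row immediately
    adjacent on either side (gaps conjoined to the tract); non-adjacent gaps
    do not extend it.
    """
    row = aln.row(focal_taxon)
    cols = []
    k = 0  # ungapped codon index
    for col, codon in enumerate(row):
        if codon == GAP_CODON:
            continue
        if focal_tract.start_codon <= k < focal_tract.end_codon:
            if codon != focal_tract.codons[k - focal_tract.start_codon]:
                raise ValueError(
                    f"tract not found in {focal_taxon}: codon mismatch at "
                    f"alignment column {col + 1}"
                )
            cols.append(col)
        k += 1
    if len(cols) != len(focal_tract):
        raise ValueError(f"tract not found in focal row {focal_taxon}")
    lo, hi = cols[0], cols[-1] + 1
    while lo > 0 and row[lo - 1] == GAP_CODON:
        lo -= 1
    while hi < aln.n_sites and row[hi] == GAP_CODON:
        hi += 1
    return lo, hi


def extract_ortholog_tract(aln_row: list[str], window: tuple[int, int],
                           gene: str = "", taxon: str = "") -> Tract | None:
    """Longest Q run in an ortholog row overlapping the focal window.

    Runs are maximal stretches of Q codons consecutive in the ortholog's
    *ungapped* sequence (gap columns do not interrupt a run). Among runs
    whose alignment columns intersect ``window``, the longest is returned;
    equal lengths tie-break to the most 5' run. None when no run overlaps.
    """
    lo, hi = window
    runs: list[tuple[int, int, list[int], list[str]]] = []  # (start_k, end_k, cols, codons)
    cur_cols: list[int] = []
    cur_codons: list[str] = []
    cur_start = 0
    k = 0
    for col, codon in enumerate(aln_row):
        if codon == GAP_CODON:
            continue
        if codon in Q_CODONS:
            if not cur_codons:
                cur_start = k
            cur_cols.append(col)
            cur_codons.append(codon)
        else:
            if cur_codons:
                runs.append((cur_start, k, cur_cols, cur_codons))
                cur_cols, cur_codons = [], []
        k += 1
    if cur_codons:
        runs.append((cur_start, k, cur_cols, cur_codons))
    overlapping = [
        r for r in runs if any(lo <= c < hi for c in r[2])
    ]
    if not overlapping:
        return None
    best = max(overlapping, key=lambda r: (len(r[3]), -r[2][0]))
    return Tract(gene, taxon, best[0], best[1], tuple(best[3]))


def tract_zscores(focal: TractRecord, orthologs: list[TractRecord]) -> TractZScores:
    """Standardize the focal tract's metrics against its ortholog set.

    Uses the sample standard deviation (n-1 denominator) of the ortholog
    values, focal excluded. A metric with zero ortholog spread yields an
    undefined (None) z rather than an infinite one.
    """
    if len(orthologs) < 2:
        raise ValueError(f"need >= 2 ortholog records, got {len(orthologs)}")

    def z(metric: str) -> float | None:
        vals = np.array([getattr(o, metric) for o in orthologs], dtype=float)
        if np.all(vals == vals[0]):  # zero spread, not a rounding artifact
            return None
        return float((getattr(focal, metric) - vals.mean()) / vals.std(ddof=1))

    return TractZScores(z("LQ"), z("LNI"), z("PQ"), n_orthologs=len(orthologs))


def filter_conserved_tracts(
    tract_sets: dict[str, dict[str, Tract]],
    taxonomy: dict[str, str],
    focal_taxon: str | None = None,
    min_primates: int = 5,
    min_nonprimates: int = 5,
    variation: str = "lq",
) -> dict[str, dict[str, Tract]]:
    """Conservation filter on per-gene (or per-tract) ortholog collections.

    Keeps a tract set when its orthologs occur in strictly more than
    ``min_primates`` primate and ``min_nonprimates`` non-primate genomes and
    show length variability: at least two distinct LQ values
    (``variation="lq"``, default) or two distinct codon strings
    (``variation="codons"``). The focal taxon, when given, is excluded from
    both counts and the variability check.
    """
    if variation not in {"lq", "codons"}:
        raise ValueError("variation must be 'lq' or 'codons'")
    kept: dict[str, dict[str, Tract]] = {}
    for key, by_taxon in tract_sets.items():
        orth = {t: tr for t, tr in by_taxon.items() if t != focal_taxon}
        for t in orth:
            if t not in taxonomy:
                raise ValueError(f"taxon {t!r} has no primate/non-primate label")
        n_pri = sum(1 for t in orth if taxonomy[t] == "primate")
        n_non = sum(1 for t in orth if taxonomy[t] != "primate")
        if n_pri <= min_primates or n_non <= min_nonprimates:
            continue
        if variation == "lq":
            distinct = {len(tr) for tr in orth.values()}
        else:
            distinct = {"".join(tr.codons) for tr in orth.values()}
        if len(distinct) < 2:
            continue
        kept[key] = by_taxon
    return kept


def rank_outliers(scores: dict[str, TractZScores]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank tracts per metric by descending z with empirical percentiles.

    Returns ``(ranked, undefined)``: the ranked table has one row per
    (key, metric) with rank 1 = largest z and percentile = rank / n_defined;
    undefined (zero-spread) scores are listed separately and never enter a
    ranking. Ties keep stable input order.
    """
    ranked_rows, undef_rows = [], []
    for metric in ("z_LQ", "z_LNI", "z_PQ"):
        defined = [(k, getattr(s, metric)) for k, s in scores.items()
                   if getattr(s, metric) is not None]
        for k, s in scores.items():
            if getattr(s, metric) is None:
                undef_rows.append({"key": k, "metric": metric})
        order = sorted(range(len(defined)), key=lambda i: -defined[i][1])
        n = len(defined)
        for rank, i in enumerate(order, start=1):
            k, z = defined[i]
            ranked_rows.append(
                {"key": k, "metric": metric, "z": z, "rank": rank,
                 "percentile": rank / n}
            )
    ranked = pd.DataFrame(ranked_rows, columns=["key", "metric", "z", "rank", "percentile"])
    undefined = pd.DataFrame(undef_rows, columns=["key", "metric"])
    return ranked, undefined


def tracts_from_alignment(aln: CodonAlignment, focal_taxon: str, gene: str = "",
                          min_len: int = 4) -> dict[str, dict[str, Tract]]:
    """Map every focal tract of one gene alignment across its orthologs.

    Detects tracts in the focal row, builds each tract's alignment window
    (conjoined gaps included) and extracts the longest overlapping Q run per
    ortholog. Returns {tract_key: {taxon: Tract}} with one entry per focal
    tract; genes with several tracts yield several independent entries.
    """
    focal_cds = "".join(aln.ungapped_codons(focal_taxon))
    out: dict[str, dict[str, Tract]] = {}
    for t_idx, tract in enumerate(
        find_polyq_tracts(focal_cds, min_len=min_len, gene=gene, taxon=focal_taxon)
    ):
        window = map_tract_window(aln, focal_taxon, tract)
        by_taxon: dict[str, Tract] = {focal_taxon: tract}
        for taxon in aln.taxa:
            if taxon == focal_taxon:
                continue
            orth = extract_ortholog_tract(aln.row(taxon), window, gene=gene, taxon=taxon)
            if orth is not None:
                by_taxon[taxon] = orth
        out[f"{gene or focal_taxon}:tract{t_idx + 1}"] = by_taxon
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PolyQOutlierModel:
    """Cross-ortholog polyQ conservation analysis for a focal taxon.

    Parameters
    ----------
    tract_table : DataFrame with columns ``gene``, ``taxon``, ``codons``
        (the tract's concatenated CAG/CAA codon string), one row per tract
        occurrence. Build it from alignments with
        :func:`tracts_from_alignment` or from a TSV of the same shape.
    taxonomy : mapping taxon -> ``"primate"`` / ``"non-primate"``.
    focal_taxon : the taxon whose tracts are standardized against the rest.
    """

    def __init__(self, tract_table: pd.DataFrame, taxonomy: dict[str, str],
                 focal_taxon: str):
        required = {"gene", "taxon", "codons"}
        if not required.issubset(tract_table.columns):
            raise ValueError(f"tract_table needs columns {sorted(required)}")
        self.tract_table = tract_table.reset_index(drop=True)
        self.taxonomy = dict(taxonomy)
        self.focal_taxon = focal_taxon

    def _tract_sets(self) -> dict[str, dict[str, Tract]]:
        sets: dict[str, dict[str, Tract]] = {}
        for _, row in self.tract_table.iterrows():
            codons = tuple(split_codons(str(row["codons"]).upper()))
            tr = Tract(row["gene"], row["taxon"], 0, len(codons), codons)
            sets.setdefault(row["gene"], {})[row["taxon"]] = tr
        return sets

    def fit(self, min_primates: int = 5, min_nonprimates: int = 5,
            variation: str = "lq") -> "PolyQOutlierResults":
        sets = filter_conserved_tracts(
            self._tract_sets(), self.taxonomy, focal_taxon=self.focal_taxon,
            min_primates=min_primates, min_nonprimates=min_nonprimates,
            variation=variation,
        )
        metric_rows = []
        zscores: dict[str, TractZScores] = {}
        for gene, by_taxon in sets.items():
            if self.focal_taxon not in by_taxon:
                continue
            recs = {t: tract_metrics(tr) for t, tr in by_taxon.items()}
            for t, rec in recs.items():
                metric_rows.append(
                    {"gene": gene, "taxon": t, "LQ": rec.LQ, "LNI": rec.LNI,
                     "PQ": rec.PQ}
                )
            orth = [rec for t, rec in recs.items() if t != self.focal_taxon]
            zscores[gene] = tract_zscores(recs[self.focal_taxon], orth)
        ranked, undefined = rank_outliers(zscores)
        return PolyQOutlierResults(self, sets, pd.DataFrame(metric_rows),
                                   zscores, ranked, undefined)


class PolyQOutlierResults:
    """Fitted tract-conservation analysis.

    Attributes
    ----------
    metrics : per (gene, taxon) LQ/LNI/PQ table.
    zscores : per-gene focal z-scores as a DataFrame.
    ranking : long table of per-metric descending ranks and percentiles.
    undefined : (gene, metric) pairs with zero ortholog spread.
    """

    def __init__(self, model, tract_sets, metrics, zscores, ranking, undefined):
        self.model = model
        self.tract_sets = tract_sets
        self.metrics = metrics
        self._zscores = zscores
        self.ranking = ranking
        self.undefined = undefined

    @property
    def zscores(self) -> pd.DataFrame:
        rows = []
        for gene, z in self._zscores.items():
            rows.append({"gene": gene, "z_LQ": z.z_LQ, "z_LNI": z.z_LNI,
                         "z_PQ": z.z_PQ, "n_orthologs": z.n_orthologs})
        return pd.DataFrame(rows, columns=["gene", "z_LQ", "z_LNI", "z_PQ",
                                           "n_orthologs"])

    def rank_of(self, gene: str, metric: str = "z_LQ") -> int:
        sub = self.ranking[(self.ranking["key"] == gene)
                           & (self.ranking["metric"] == metric)]
        if sub.empty:
            raise KeyError(f"{gene} has no defined {metric}")
        return int(sub["rank"].iloc[0])

    def summary(self) -> str:
        z = self.zscores
        lines = [
            "PolyQ tract conservation analysis",
            f"  focal taxon: {self.model.focal_taxon}",
            f"  tract sets passing conservation filter: {len(self.tract_sets)}",
            f"  tracts with defined z-scores: "
            f"LQ={z['z_LQ'].notna().sum()}, LNI={z['z_LNI'].notna().sum()}, "
            f"PQ={z['z_PQ'].notna().sum()}",
            "",
            z.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)
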