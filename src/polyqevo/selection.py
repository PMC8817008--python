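"""Counting-based per-site synonymous/non-synonymous selection inference.

The estimator is a single-ancestor counting method in the SLAC family:
ancestral codon states are reconstructed by maximum parsimony (codons as
atomic states), substitutions on every branch are converted to synonymous
(S) and non-synonymous (N) counts by averaging over all orderings of the
differing codon positions — pathways passing through a stop codon are
excluded, the Nei–Gojobori convention — and equally parsimonious ancestral
assignments are averaged uniformly. Expected synonymous/non-synonymous site
counts (ES, EN) per codon are normalized over non-stop single-nucleotide
neighbors so that ES + EN = 3 exactly.

Per site, a binomial test compares the observed synonymous fraction with
the neutral expectation p0 = ES/(ES+EN): an excess of synonymous changes
signals purifying (negative) selection, an excess of non-synonymous changes
diversifying (positive) selection. Branch lengths are ignored: the counting
estimator needs states, not times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import binom

from polyqevo._codons import CODON_TABLE, STOP_CODONS, translate_codon
from polyqevo.seqio import CodonAlignment, read_newick, read_nexus, read_fasta, reconcile

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Codon-level primitives
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def expected_sites(codon: str) -> tuple[float, float]:
    """Expected synonymous (ES) and non-synonymous (EN) site counts.

    Per codon position the synonymous fraction is the number of synonymous
    single-nucleotide alternatives over the number of non-stop alternatives;
    ES is the sum over the three positions and EN = 3 - ES.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no expected sites: {codon}")
    aa = translate_codon(codon)  # raises on non-codon input
    es = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            nonstop += 1
            if CODON_TABLE[alt] == aa:
                syn += 1
        if nonstop:
            es += syn / nonstop
    return es, 3.0 - es


@lru_cache(maxsize=None)
def count_pathway_changes(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/non-synonymous counts between two sense codons.

    Averages S and N over all orderings of the differing positions, skipping
    any pathway that passes through a stop codon; when at least one pathway
    survives, S + N equals the number of differing positions. If every
    pathway is blocked by stops, falls back to an unordered per-position
    comparison (logged).
    """
    for c in (codon_a, codon_b):
        if c not in CODON_TABLE:
            raise ValueError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff):
        cur = codon_a
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            pathways.append((s, n))
    if pathways:
        return (
            sum(p[0] for p in pathways) / len(pathways),
            sum(p[1] for p in pathways) / len(pathways),
        )
    logger.warning(
        "all pathways %s -> %s pass through stops; per-position fallback",
        codon_a, codon_b,
    )
    s = n = 0
    for pos in diff:
        alt = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1:]
        if alt not in STOP_CODONS and CODON_TABLE[alt] == CODON_TABLE[codon_a]:
            s += 1
        else:
            n += 1
    return float(s), float(n)


# ---------------------------------------------------------------------------
# Ancestral reconstruction and per-site counting
# ---------------------------------------------------------------------------

@dataclass
class SiteCounts:
    """Observed and expected substitution counts at one codon column."""

    site: int
    S_obs: float
    N_obs: float
    ES: float
    EN: float
    n_codons: int  # observed (non-missing) leaf codons at the site
    min_changes: int  # parsimony score of the column


def reconstruct_ancestors(aln: CodonAlignment, tree: dendropy.Tree
                          ) -> list[dict[dendropy.Node, frozenset[str]]]:
    """Per-site Fitch parsimony state sets for every internal node.

    Codons are atomic states; leaves with gap or ambiguous codons are
    missing data for that site and excluded. The returned per-site mapping
    holds, for each node with data beneath it, the set of states attained by
    at least one minimum-change labeling.
    """
    _check_leaves(aln, tree)
    out = []
    for site in range(aln.n_sites):
        leaf_state = _leaf_states(aln, site)
        tables = _site_tables(tree, leaf_state)
        root_tab = tables.get(tree.seed_node)
        site_sets: dict[dendropy.Node, frozenset[str]] = {}
        if root_tab:
            gmin = min(c for c, *_ in root_tab.values())
            optimal_root = {s for s, (c, *_rest) in root_tab.items() if c == gmin}
            site_sets = _optimal_state_sets(tree, tables, optimal_root)
        out.append(site_sets)
    return out


def _check_leaves(aln: CodonAlignment, tree: dendropy.Tree) -> None:
    missing = [lf.taxon.label for lf in tree.leaf_node_iter()
               if lf.taxon.label not in aln.rows]
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {', '.join(missing)}")


def _leaf_states(aln: CodonAlignment, site: int) -> dict[str, str | None]:
    states = {}
    for t in aln.taxa:
        c = aln.rows[t][site]
        states[t] = c if c in CODON_TABLE else None
    return states


def _site_tables(tree: dendropy.Tree, leaf_state: dict[str, str | None]):
    """Sankoff-style DP with unit codon-change cost.

    For each node and candidate state s the table holds
    ``(min_cost, n_labelings, sum_S, sum_N)`` over all minimum-cost
    labelings of the subtree given the node is in state s; sum_S/sum_N
    accumulate pathway-averaged synonymous / non-synonymous counts over the
    subtree's branches. Dataless subtrees carry no table.
    """
    alphabet = sorted({s for s in leaf_state.values() if s is not None})
    tables: dict[dendropy.Node, dict[str, tuple[float, int, float, float]] | None] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            st = leaf_state.get(node.taxon.label)
            tables[node] = None if st is None else {st: (0.0, 1, 0.0, 0.0)}
            continue
        childs = [tables[c] for c in node.child_nodes() if tables[c] is not None]
        if not childs:
            tables[node] = None
            continue
        tab: dict[str, tuple[float, int, float, float]] = {}
        for s in alphabet:
            cost = 0.0
            ways_per_child: list[int] = []
            s_per_child: list[float] = []
            n_per_child: list[float] = []
            for ct in childs:
                best = math.inf
                for t, (c, *_r) in ct.items():
                    e = c + (0.0 if t == s else 1.0)
                    if e < best:
                        best = e
                w = 0
                ssum = nsum = 0.0
                for t, (c, wways, sS, sN) in ct.items():
                    if c + (0.0 if t == s else 1.0) == best:
                        dS, dN = count_pathway_changes(s, t)
                        w += wways
                        ssum += sS + dS * wways
                        nsum += sN + dN * wways
                cost += best
                ways_per_child.append(w)
                s_per_child.append(ssum)
                n_per_child.append(nsum)
            total_ways = 1
            for w in ways_per_child:
                total_ways *= w
            sumS = sumN = 0.0
            for i in range(len(childs)):
                others = 1
                for j, w in enumerate(ways_per_child):
                    if j != i:
                        others *= w
                sumS += s_per_child[i] * others
                sumN += n_per_child[i] * others
            tab[s] = (cost, total_ways, sumS, sumN)
        tables[node] = tab
    return tables


def _optimal_state_sets(tree, tables, optimal_root):
    """Top-down pass retaining every state used by some optimal labeling."""
    keep: dict[dendropy.Node, frozenset[str]] = {}
    keep[tree.seed_node] = frozenset(optimal_root)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or tables.get(node) is None:
            continue
        parent = node.parent_node
        while parent is not None and tables.get(parent) is None:
            parent = parent.parent_node
        parent_states = keep.get(parent, frozenset())
        ct = tables[node]
        states = set()
        for p in parent_states:
            best = min(c + (0.0 if t == p else 1.0) for t, (c, *_r) in ct.items())
            states |= {t for t, (c, *_r) in ct.items()
                       if c + (0.0 if t == p else 1.0) == best}
        keep[node] = frozenset(states)
    return {n: s for n, s in keep.items() if tables.get(n) is not None}


def slac_site_counts(aln: CodonAlignment, tree: dendropy.Tree) -> list[SiteCounts]:
    """Per-site observed S/N counts and expected site counts.

    Observed counts sum pathway-averaged changes over all branches,
    averaging uniformly over every equally parsimonious ancestral
    assignment; ES/EN average the per-codon expected sites over all observed
    leaf codons at the column.
    """
    _check_leaves(aln, tree)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out = []
    for site in range(aln.n_sites):
        leaf_state = {t: s for t, s in _leaf_states(aln, site).items()
                      if t in leaf_labels}
        observed = [s for s in leaf_state.values() if s is not None]
        if observed:
            pairs = [expected_sites(c) for c in observed]
            es = sum(p[0] for p in pairs) / len(pairs)
            en = sum(p[1] for p in pairs) / len(pairs)
        else:
            es = en = 0.0
        s_obs = n_obs = 0.0
        min_changes = 0
        if len(set(observed)) > 1:
            tables = _site_tables(tree, leaf_state)
            root_tab = tables.get(tree.seed_node)
            gmin = min(c for c, *_r in root_tab.values())
            ways = sum(w for c, w, _s, _n in root_tab.values() if c == gmin)
            s_tot = sum(s for c, _w, s, _n in root_tab.values() if c == gmin)
            n_tot = sum(n for c, _w, _s, n in root_tab.values() if c == gmin)
            s_obs = s_tot / ways
            n_obs = n_tot / ways
            min_changes = int(gmin)
        out.append(SiteCounts(site, s_obs, n_obs, es, en, len(observed), min_changes))
    return out


# ---------------------------------------------------------------------------
# Binomial site test and summaries
# ---------------------------------------------------------------------------

@dataclass
class SiteSelectionRecord:
    """Per-site selection inference: rates, test p-values, classification."""

    site: int
    S_obs: float
    N_obs: float
    ES: float
    EN: float
    dN: float
    dS: float
    ratio: float  # dN/dS; NaN when undefined (dS = 0 or no data)
    p_negative: float
    p_positive: float
    classification: str  # negative | positive | neutral


def slac_site_test(c: SiteCounts, alpha: float = 0.1) -> SiteSelectionRecord:
    """Binomial test of the observed synonymous fraction at one site.

    With n the nearest integer of S_obs + N_obs and p0 = ES/(ES+EN):
    ``p_negative`` is the upper-tail probability of at least the observed
    synonymous count under Binomial(n, p0); ``p_positive`` the analogous
    tail for non-synonymous counts. Fractional counts enter the tails via
    their ceiling but are retained unrounded in the report.
    """
    total = c.ES + c.EN
    p0 = c.ES / total if total > 0 else 0.0
    n = int(round(c.S_obs + c.N_obs))
    if n == 0:
        p_neg = p_pos = 1.0
    else:
        k_s = min(n, math.ceil(c.S_obs - 1e-9))
        k_n = min(n, math.ceil(c.N_obs - 1e-9))
        p_neg = float(binom.sf(k_s - 1, n, p0))
        p_pos = float(binom.sf(k_n - 1, n, 1.0 - p0))
    dn = c.N_obs / c.EN if c.EN > 0 else math.nan
    ds = c.S_obs / c.ES if c.ES > 0 else math.nan
    ratio = dn / ds if (ds and not math.isnan(ds) and not math.isnan(dn)) else math.nan
    if n == 0:
        cls = "neutral"
    elif p_neg <= alpha and p_neg <= p_pos:
        cls = "negative"
    elif p_pos <= alpha:
        cls = "positive"
    else:
        cls = "neutral"
    return SiteSelectionRecord(c.site, c.S_obs, c.N_obs, c.ES, c.EN,
                               dn, ds, ratio, p_neg, p_pos, cls)


@dataclass
class RegionSummary:
    """Aggregate selection summary over a codon-column interval."""

    S_total: float
    N_total: float
    n_sites: int  # region sites with data
    n_sites_negative: int
    fraction_negative: float


def region_summary(records: list[SiteSelectionRecord],
                   region: tuple[int, int]) -> RegionSummary:
    """Totals and purifying fraction over ``region`` (0-based half-open)."""
    lo, hi = region
    sub = [r for r in records if lo <= r.site < hi]
    if not sub:
        raise ValueError(f"empty region [{lo}, {hi})")
    with_data = [r for r in sub if r.ES + r.EN > 0]
    n_neg = sum(1 for r in with_data if r.classification == "negative")
    frac = n_neg / len(with_data) if with_data else 0.0
    return RegionSummary(
        S_total=sum(r.S_obs for r in sub),
        N_total=sum(r.N_obs for r in sub),
        n_sites=len(with_data),
        n_sites_negative=n_neg,
        fraction_negative=frac,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SiteSelectionModel:
    """Per-site purifying/diversifying selection test on a codon alignment.

    Parameters
    ----------
    alignment : CodonAlignment reconciled with ``tree`` (exact label match;
        unmatched taxa are pruned with a warning).
    tree : rooted dendropy tree whose leaf labels name alignment rows.
    """

    def __init__(self, alignment: CodonAlignment, tree: dendropy.Tree):
        self.alignment, self.tree = reconcile(alignment, tree)

    @classmethod
    def from_nexus(cls, path) -> "SiteSelectionModel":
        aln, tree = read_nexus(path)
        return cls(aln, tree)

    @classmethod
    def from_files(cls, fasta_path, newick_path) -> "SiteSelectionModel":
        seqs = read_fasta(fasta_path)
        aln = CodonAlignment.from_sequences(seqs, coding=False)
        return cls(aln, read_newick(newick_path))

    def fit(self, alpha: float = 0.1) -> "SiteSelectionResults":
        counts = slac_site_counts(self.alignment, self.tree)
        records = [slac_site_test(c, alpha=alpha) for c in counts]
        return SiteSelectionResults(self, counts, records, alpha)


class SiteSelectionResults:
    """Fitted per-site selection analysis.

    ``frame`` exposes the full per-site table; ``region_summary`` aggregates
    an interval (e.g. the polyQ window); ``plot`` mirrors the classic
    per-codon S/N bar panel.
    """

    def __init__(self, model, counts, records, alpha):
        self.model = model
        self.counts = counts
        self.records = records
        self.alpha = alpha

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site": r.site + 1,  # 1-based in user-facing tables
                    "S_obs": r.S_obs, "N_obs": r.N_obs,
                    "ES": r.ES, "EN": r.EN,
                    "dN": r.dN, "dS": r.dS, "dN_dS": r.ratio,
                    "p_negative": r.p_negative, "p_positive": r.p_positive,
                    "classification": r.classification,
                }
                for r in self.records
            ]
        )

    def region_summary(self, region: tuple[int, int]) -> RegionSummary:
        return region_summary(self.records, region)

    def summary(self, region: tuple[int, int] | None = None) -> str:
        n_neg = sum(1 for r in self.records if r.classification == "negative")
        n_pos = sum(1 for r in self.records if r.classification == "positive")
        s_tot = sum(r.S_obs for r in self.records)
        n_tot = sum(r.N_obs for r in self.records)
        lines = [
            "Per-site selection analysis (pathway-counting estimator)",
            f"  taxa: {len(self.model.alignment.taxa)}    "
            f"codon sites: {self.model.alignment.n_sites}    alpha: {self.alpha}",
            f"  total substitutions: synonymous={s_tot:.2f} "
            f"non-synonymous={n_tot:.2f}",
            f"  sites under purifying selection: {n_neg}",
            f"  sites under diversifying selection: {n_pos}",
        ]
        if region is not None:
            rs = self.region_summary(region)
            lines += [
                f"  region [{region[0] + 1}-{region[1]}] (1-based): "
                f"S={rs.S_total:.2f} N={rs.N_total:.2f} "
                f"purifying {rs.n_sites_negative}/{rs.n_sites} "
                f"({100 * rs.fraction_negative:.1f}%)",
            ]
        return "\n".join(lines)

    def plot(self, ax=None, region: tuple[int, int] | None = None):
        """Per-codon synonymous/non-synonymous substitution bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        sites = np.array([r.site + 1 for r in self.records])
        ax.bar(sites - 0.2, [r.S_obs for r in self.records], width=0.4,
               color="seagreen", label="synonymous")
        ax.bar(sites + 0.2, [r.N_obs for r in self.records], width=0.4,
               color="steelblue", label="non-synonymous")
        if region is not None:
            ax.axvspan(region[0] + 0.5, region[1] + 0.5, color="0.85", zorder=0)
        ax.set_xlabel("codon site")
        ax.set_ylabel("substitutions")
        ax.legend()
        return ax
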