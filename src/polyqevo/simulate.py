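"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study design the analyses assume:

* codon sequences evolving on a phylogeny under an HKY-style mutation
  process with per-site selection classes — a non-synonymous proposal is
  accepted with probability min(1, omega) of the site's class, so the truth
  table records exact synonymous/non-synonymous substitution counts;
* a CAG/CAA repeat region evolving by expansion, contraction and CAG<->CAA
  interruption events, mirroring the instability of pure CAG tracts;
* ortholog tract tables (primate and non-primate genomes) with one planted
  outlier taxon carrying a longer, purer tract;
* pseudogene/reference/outgroup triples with uniform or exon-biased
  mutation rates;
* RNA-seq-like count matrices for the 0Q/2Q/4Q/7Q genotype series with a
  planted fraction of monotonically Q-responsive genes (multiplicative
  per-step effect, log-normal noise), three replicates per genotype.

Every generator takes an explicit seed and no global state is touched:
identical parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from polyqevo._codons import CODON_TABLE, GAP_CODON, STOP_CODONS, split_codons
from polyqevo.seqio import CodonAlignment

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def balanced_tree(n_taxa: int, branch_length: float = 0.1) -> dendropy.Tree:
    """Balanced (caterpillar-free) binary tree with uniform branch lengths."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]

    def build(names: list[str]) -> str:
        if len(names) == 1:
            return f"{names[0]}:{branch_length}"
        mid = len(names) // 2
        return f"({build(names[:mid])},{build(names[mid:])}):{branch_length}"

    newick = build(labels)[: -len(f":{branch_length}")] + ";"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _label_internal(tree: dendropy.Tree) -> None:
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is None:
            k += 1
            node.label = f"node{k}"


# ---------------------------------------------------------------------------
# Codon evolution with selection classes
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Conditions for the codon-evolution generator.

    ``site_classes`` gives (omega, fraction) pairs; fractions must sum to 1.
    ``branch_length`` is the expected number of mutation proposals per
    nucleotide site per branch when no tree is supplied. The optional
    ``repeat_region`` (codon interval, 0-based half-open, within the root
    sequence) evolves by the repeat machinery instead of point proposals.
    """

    seed: int
    n_taxa: int = 16
    branch_length: float = 0.1
    tree: dendropy.Tree | None = None
    kappa: float = 2.0
    site_classes: tuple[tuple[float, float], ...] = ((0.1, 0.5), (1.0, 0.5))
    repeat_region: tuple[int, int] | None = None
    expand_rate: float = 0.0
    contract_rate: float = 0.0
    caa_interrupt_prob: float = 0.0

    def __post_init__(self):
        total = sum(f for _, f in self.site_classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"site-class fractions sum to {total}, not 1")
        if min(self.expand_rate, self.contract_rate, self.caa_interrupt_prob) < 0:
            raise ValueError("repeat rates must be >= 0")


def _propose(codon: str, rng: np.random.Generator, kappa: float) -> tuple[int, str]:
    pos = int(rng.integers(3))
    current = codon[pos]
    alts = [nt for nt in "ACGT" if nt != current]
    w = np.array([kappa if _TRANSITIONS[current] == nt else 1.0 for nt in alts])
    nt = alts[int(rng.choice(3, p=w / w.sum()))]
    return pos, nt


def mutate_repeat(tract: list[str], rng: np.random.Generator,
                  expand_rate: float, contract_rate: float,
                  caa_interrupt_prob: float) -> list[str]:
    """One branch of repeat evolution on a CAG/CAA tract.

    Expansion inserts a copy of a random unit next to itself, contraction
    deletes a random unit (skipped on a length-1 tract), and each unit then
    flips CAG<->CAA with probability ``caa_interrupt_prob``. Output codons
    remain in {CAA, CAG}.
    """
    if any(c not in ("CAA", "CAG") for c in tract):
        raise ValueError("repeat tract must contain only CAA/CAG codons")
    tract = list(tract)
    for _ in range(rng.poisson(expand_rate)):
        i = int(rng.integers(len(tract)))
        tract.insert(i + 1, tract[i])
    for _ in range(rng.poisson(contract_rate)):
        if len(tract) <= 1:
            continue
        del tract[int(rng.integers(len(tract)))]
    if caa_interrupt_prob > 0:
        flips = rng.random(len(tract)) < caa_interrupt_prob
        tract = [
            ("CAA" if c == "CAG" else "CAG") if f else c
            for c, f in zip(tract, flips)
        ]
    return tract


def evolve_codon_sequences(p: SimParams, root_cds: str
                           ) -> tuple[CodonAlignment, dendropy.Tree, dict]:
    """Evolve a root CDS down a tree; return alignment, tree and truth.

    Point proposals follow an HKY-style kernel (transitions weighted by
    kappa); proposals creating stop codons are rejected and non-synonymous
    proposals are accepted with probability min(1, omega) of the site's
    class. The truth dict carries ``substitutions`` (branch, site, from, to,
    syn) and ``site_omega``; with a repeat region it also carries the leaf
    tract lengths. The repeat region is left-justified and gap-padded to
    its maximum evolved length in the output alignment.
    """
    rng = np.random.default_rng(p.seed)
    tree = p.tree if p.tree is not None else balanced_tree(p.n_taxa, p.branch_length)
    _label_internal(tree)
    root_codons = split_codons(root_cds.upper())
    for i, c in enumerate(root_codons):
        if c in STOP_CODONS:
            raise ValueError(f"root CDS has a stop codon at codon {i + 1}")
    n_sites = len(root_codons)
    repeat = p.repeat_region
    if repeat is not None:
        lo, hi = repeat
        root_tract = root_codons[lo:hi]
        if any(c not in ("CAA", "CAG") for c in root_tract):
            raise ValueError("repeat_region of the root must be CAA/CAG codons")
        point_sites = [i for i in range(n_sites) if not lo <= i < hi]
    else:
        root_tract = []
        point_sites = list(range(n_sites))

    omegas, fracs = zip(*p.site_classes)
    site_omega = np.full(n_sites, np.nan)
    site_omega[point_sites] = rng.choice(
        omegas, size=len(point_sites), p=np.array(fracs)
    )

    subs = []
    leaf_codons: dict[str, list[str]] = {}
    leaf_tracts: dict[str, list[str]] = {}

    def descend(node, codons: list[str], tract: list[str]) -> None:
        for child in node.child_nodes():
            c_codons = list(codons)
            c_tract = list(tract)
            t = child.edge.length if child.edge.length is not None else p.branch_length
            child_label = child.taxon.label if child.is_leaf() else child.label
            for site in point_sites:
                n_prop = rng.poisson(3.0 * t)
                for _ in range(n_prop):
                    pos, nt = _propose(c_codons[site], rng, p.kappa)
                    old = c_codons[site]
                    new = old[:pos] + nt + old[pos + 1:]
                    if new == old or new in STOP_CODONS:
                        continue
                    syn = CODON_TABLE[old] == CODON_TABLE[new]
                    if not syn and rng.random() >= min(1.0, site_omega[site]):
                        continue
                    c_codons[site] = new
                    subs.append(
                        {"branch": child_label, "site": site, "from": old,
                         "to": new, "syn": syn}
                    )
            if repeat is not None:
                # expansion/contraction/interruption rates are per branch
                c_tract = mutate_repeat(
                    c_tract, rng, p.expand_rate, p.contract_rate,
                    p.caa_interrupt_prob,
                )
            if child.is_leaf():
                leaf_codons[child.taxon.label] = c_codons
                leaf_tracts[child.taxon.label] = c_tract
            else:
                descend(child, c_codons, c_tract)

    descend(tree.seed_node, root_codons, root_tract)

    taxa = sorted(leaf_codons)
    if repeat is not None:
        lo, hi = repeat
        width = max(len(leaf_tracts[t]) for t in taxa)
        rows = {}
        for t in taxa:
            tract = leaf_tracts[t]
            padded = tract + [GAP_CODON] * (width - len(tract))
            rows[t] = leaf_codons[t][:lo] + padded + leaf_codons[t][hi:]
    else:
        rows = {t: leaf_codons[t] for t in taxa}
    aln = CodonAlignment(taxa, rows, coding=False)
    truth = {
        "substitutions": pd.DataFrame(
            subs, columns=["branch", "site", "from", "to", "syn"]
        ),
        "site_omega": pd.DataFrame(
            {"site": range(n_sites), "omega": site_omega}
        ),
        "leaf_tract_length": {t: len(leaf_tracts[t]) for t in taxa}
        if repeat is not None else {},
    }
    return aln, tree, truth


def neutral_root_cds(n_codons: int, seed: int) -> str:
    """Random sense-codon CDS (no stops) for seeding simulations."""
    rng = np.random.default_rng(seed)
    sense = sorted(CODON_TABLE)
    return "".join(rng.choice(sense) for _ in range(n_codons))


# ---------------------------------------------------------------------------
# Ortholog tract tables with a planted outlier
# ---------------------------------------------------------------------------

@dataclass
class OutlierSpec:
    """Planted outlier: one taxon with a boosted, optionally pure, tract.

    ``genes`` restricts the boost to the named genes; None boosts every
    gene (the planted taxon is an outlier throughout).
    """

    taxon: str
    boost_lq: int = 14
    pure: bool = True
    genes: tuple[str, ...] | None = None


@dataclass
class TractSimParams:
    """Conditions for ortholog tract-table generation.

    Defaults mirror a mammalian ortholog panel: 8 primate plus 8 non-primate
    genomes, tract lengths around 7 Q (the murine HTT length) with spread 2,
    and 70% CAG among Q codons.
    """

    seed: int
    n_genes: int = 20
    n_primates: int = 8
    n_nonprimates: int = 8
    mean_lq: float = 7.0
    sd_lq: float = 2.0
    cag_prob: float = 0.7
    min_lq: int = 4


def make_tract_dataset(p: TractSimParams, outlier: OutlierSpec | None = None
                       ) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Ortholog tract table with an optional planted outlier taxon.

    Returns (tract_table, taxonomy, truth). The planted taxon's tract in
    every gene is ``boost_lq`` codons longer than a draw from the ortholog
    length distribution and pure CAG when requested, so it should dominate
    downstream LQ/LNI rankings. ``truth`` records the planted taxon and per
    gene/taxon lengths.
    """
    rng = np.random.default_rng(p.seed)
    primates = [f"primate{i + 1}" for i in range(p.n_primates)]
    nonprimates = [f"nonprimate{i + 1}" for i in range(p.n_nonprimates)]
    taxa = primates + nonprimates
    taxonomy = {t: "primate" for t in primates}
    taxonomy.update({t: "non-primate" for t in nonprimates})
    if outlier is not None and outlier.taxon not in taxonomy:
        taxonomy[outlier.taxon] = "primate"
        taxa = [outlier.taxon] + taxa

    def draw_lq() -> int:
        return max(p.min_lq, int(round(rng.normal(p.mean_lq, p.sd_lq))))

    rows = []
    lengths: dict[tuple[str, str], int] = {}
    for g in range(p.n_genes):
        gene = f"gene{g + 1}"
        for taxon in taxa:
            lq = draw_lq()
            pure = False
            if (outlier is not None and taxon == outlier.taxon
                    and (outlier.genes is None or gene in outlier.genes)):
                lq += outlier.boost_lq
                pure = outlier.pure
            if pure:
                codons = ["CAG"] * lq
            else:
                codons = ["CAG" if x < p.cag_prob else "CAA"
                          for x in rng.random(lq)]
            rows.append({"gene": gene, "taxon": taxon, "codons": "".join(codons)})
            lengths[(gene, taxon)] = lq
    table = pd.DataFrame(rows, columns=["gene", "taxon", "codons"])
    truth = {"planted_taxon": outlier.taxon if outlier else None,
             "lengths": lengths}
    return table, taxonomy, truth


# ---------------------------------------------------------------------------
# Pseudogene triples
# ---------------------------------------------------------------------------

def simulate_pseudogene_triple(
    n_columns: int, seed: int, focal_rate: float = 0.05,
    reference_rate: float = 0.01, outgroup_rate: float = 0.02,
    hot_interval: tuple[int, int] | None = None, hot_factor: float = 1.0,
) -> tuple[str, str, str]:
    """Aligned (focal, reference, outgroup) triple with per-lineage rates.

    Each column starts from a shared ancestral base; each lineage substitutes
    it independently with its rate (focal columns in ``hot_interval`` use
    ``hot_factor`` times the focal rate). Substitutions pick a different base
    uniformly, so polarization recovers the focal lineage's changes up to
    homoplasy noise.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    anc = rng.choice(bases, size=n_columns)

    def mutate(seq, rate_per_col):
        out = seq.copy()
        hits = rng.random(n_columns) < rate_per_col
        for i in np.where(hits)[0]:
            out[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
        return out

    focal_rates = np.full(n_columns, focal_rate)
    if hot_interval is not None:
        lo, hi = hot_interval
        focal_rates[lo:hi] *= hot_factor
    focal = mutate(anc, focal_rates)
    reference = mutate(anc, np.full(n_columns, reference_rate))
    outgroup = mutate(anc, np.full(n_columns, outgroup_rate))
    return "".join(focal), "".join(reference), "".join(outgroup)


# ---------------------------------------------------------------------------
# Expression count matrices
# ---------------------------------------------------------------------------

@dataclass
class ExprSimParams:
    """Conditions for the genotype-series expression generator.

    Defaults follow the knock-in series design: genotypes 0/2/4/7 Q with
    three replicates each, a two-fold extreme-genotype contrast for planted
    genes (per-step effect 2^(1/3)), and multiplicative log-normal
    replicate noise with sigma 0.15 — a 15% coefficient of variation,
    typical of bulk RNA-seq biological replicates.
    """

    seed: int
    n_genes: int = 1000
    planted_fraction: float = 0.1
    genotypes: tuple[int, ...] = (0, 2, 4, 7)
    replicates: int = 3
    effect: float = 2.0 ** (1.0 / 3.0)
    sigma: float = 0.15
    base_log_mean: float = 4.0
    base_log_sd: float = 1.5
    library_sizes: tuple[float, ...] | None = None

    def __post_init__(self):
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.effect <= 0:
            raise ValueError("effect must be positive")


def simulate_counts(p: ExprSimParams
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Gene x sample abundance matrix with planted Q-length trends.

    Unplanted genes have genotype-independent means; a planted gene's mean
    is scaled by ``effect ** rank(Q)`` (rank 0..3 over the ordered
    genotypes) in a randomly chosen direction. Replicate values multiply the
    mean by exp(N(0, sigma)); when ``library_sizes`` is given, columns are
    rescaled to those totals. Returns (counts, sample_meta, truth) where
    truth labels each gene ``up``, ``down`` or ``none``.
    """
    rng = np.random.default_rng(p.seed)
    genes = [f"g{i + 1}" for i in range(p.n_genes)]
    samples, qs = [], []
    for q in p.genotypes:
        for r in range(p.replicates):
            samples.append(f"Q{q}_rep{r + 1}")
            qs.append(q)
    meta = pd.DataFrame({"sample": samples, "Q": qs,
                         "replicate": [int(s.split("rep")[1]) for s in samples]})

    base = np.exp(rng.normal(p.base_log_mean, p.base_log_sd, size=p.n_genes))
    n_planted = int(round(p.planted_fraction * p.n_genes))
    planted_idx = rng.choice(p.n_genes, size=n_planted, replace=False)
    direction = np.zeros(p.n_genes, dtype=int)
    direction[planted_idx] = rng.choice([-1, 1], size=n_planted)

    rank = {q: i for i, q in enumerate(sorted(p.genotypes))}
    means = np.empty((p.n_genes, len(samples)))
    for j, q in enumerate(qs):
        means[:, j] = base * p.effect ** (direction * rank[q])
    noise = (np.exp(rng.normal(0.0, p.sigma, size=means.shape))
             if p.sigma > 0 else 1.0)
    values = means * noise
    counts = pd.DataFrame(values, index=genes, columns=samples)
    if p.library_sizes is not None:
        if len(p.library_sizes) != len(samples):
            raise ValueError("library_sizes length must match sample count")
        counts = counts * np.asarray(p.library_sizes) / counts.sum(axis=0).to_numpy()
    truth = pd.Series(
        np.where(direction > 0, "up", np.where(direction < 0, "down", "none")),
        index=genes, name="truth",
    )
    return counts, meta, truth
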