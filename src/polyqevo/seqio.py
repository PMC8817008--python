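"""Sequence, alignment and tree I/O for the polyQ pipeline.

FASTA records go through Biopython, trees and Nexus files through dendropy.
The module's own container is :class:`CodonAlignment`: an aligned matrix of
atomic 3-letter codons per taxon, the substrate for tract mapping and
substitution counting.

Coordinates are 0-based half-open internally; user-facing messages are
1-based closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from polyqevo._codons import GAP_CODON, STOP_CODONS, split_codons, translate_codon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


class CodonAlignment:
    """Aligned codon matrix: per taxon, one codon (or ``---`` gap) per column.

    Parameters
    ----------
    taxa : ordered taxon labels.
    rows : mapping taxon -> list of codon strings, all of equal length.
    coding : if True (default), reject rows containing an internal stop codon.

    Mixed gap/nucleotide codons (e.g. ``CA-``) are rejected at construction:
    they make per-site synonymous/non-synonymous counting ill-defined.
    Ambiguity symbols (N and other IUPAC codes) are preserved; downstream
    stages treat codons containing them as missing data.
    """

    def __init__(self, taxa: list[str], rows: dict[str, list[str]], coding: bool = True):
        if not taxa:
            raise ValueError("alignment has no taxa")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels in alignment")
        n_cols = {len(rows[t]) for t in taxa}
        if len(n_cols) != 1:
            raise ValueError(f"rows have unequal codon counts: {sorted(n_cols)}")
        self.taxa = list(taxa)
        self.rows = {t: list(rows[t]) for t in taxa}
        self.n_sites = n_cols.pop()
        for t in taxa:
            self._validate_row(t, self.rows[t], coding)

    @staticmethod
    def _validate_row(taxon: str, codons: list[str], coding: bool) -> None:
        last_nongap = max(
            (i for i, c in enumerate(codons) if c != GAP_CODON), default=-1
        )
        for i, codon in enumerate(codons):
            if len(codon) != 3:
                raise ValueError(f"{taxon}: codon {i + 1} has length {len(codon)}")
            if "-" in codon and codon != GAP_CODON:
                raise ValueError(
                    f"{taxon}: codon {i + 1} ({codon!r}) mixes gap and nucleotide symbols"
                )
            if coding and codon in STOP_CODONS and i < last_nongap:
                raise ValueError(
                    f"{taxon}: internal stop codon {codon} at codon position {i + 1}"
                )

    @classmethod
    def from_sequences(cls, seqs: list[Sequence], coding: bool = True) -> "CodonAlignment":
        """Build from equal-length aligned nucleotide sequences."""
        rows = {s.id: split_codons(s.seq.upper()) for s in seqs}
        return cls([s.id for s in seqs], rows, coding=coding)

    def row(self, taxon: str) -> list[str]:
        return self.rows[taxon]

    def column(self, site: int) -> dict[str, str]:
        return {t: self.rows[t][site] for t in self.taxa}

    def ungapped_codons(self, taxon: str) -> list[str]:
        return [c for c in self.rows[taxon] if c != GAP_CODON]

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        return CodonAlignment(taxa, {t: self.rows[t] for t in taxa}, coding=False)

    def to_sequences(self) -> list[Sequence]:
        return [Sequence(t, "".join(self.rows[t])) for t in self.taxa]

    def __len__(self) -> int:
        return len(self.taxa)

    def __repr__(self) -> str:
        return f"<CodonAlignment: {len(self.taxa)} taxa x {self.n_sites} codon sites>"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[Sequence]:
    """Read a multi-record FASTA file.

    Record order is preserved; ids are taken from the header up to the first
    whitespace. Duplicate ids and empty files are errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(Sequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: list[Sequence], path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Newick / Nexus
# ---------------------------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    """Read a single Newick tree."""
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def reconcile(aln: CodonAlignment, tree: dendropy.Tree) -> tuple[CodonAlignment, dendropy.Tree]:
    """Reconcile alignment taxa and tree leaves by exact label match.

    Taxa present in only one of the two are reported (warning log) and
    pruned. Labels are compared after trimming surrounding whitespace; no
    fuzzy matching is attempted.
    """
    aln_taxa = {t.strip(): t for t in aln.taxa}
    tree_taxa = set(_leaf_labels(tree))
    tree_taxa = {t.strip() for t in tree_taxa}
    common = set(aln_taxa) & tree_taxa
    if not common:
        raise ValueError("alignment and tree share no taxon labels")
    only_aln = sorted(set(aln_taxa) - common)
    only_tree = sorted(tree_taxa - common)
    if only_aln:
        logger.warning("taxa only in alignment, pruned: %s", ", ".join(only_aln))
    if only_tree:
        logger.warning("taxa only in tree, pruned: %s", ", ".join(only_tree))
    if only_tree:
        tree.retain_taxa_with_labels(sorted(common))
    new_taxa = [t for t in aln.taxa if t.strip() in common]
    pruned = aln.subset(new_taxa) if only_aln else aln
    return pruned, tree


def read_nexus(path) -> tuple[CodonAlignment, dendropy.Tree]:
    """Read a Nexus file with a DATA/CHARACTERS block and a TREES block.

    Returns the codon alignment and the (first) embedded tree, reconciled by
    exact label match; unmatched taxa are logged and pruned.
    """
    ds = dendropy.DataSet.get(path=str(path), schema="nexus", preserve_underscores=True)
    if not ds.char_matrices:
        raise ValueError(f"{path}: no DATA/CHARACTERS block found")
    if not ds.tree_lists or not len(ds.tree_lists[0]):
        raise ValueError(
            f"{path}: no TREES block found; supply a Newick tree separately "
            "via read_newick()"
        )
    mat = ds.char_matrices[0]
    seqs = []
    for taxon in mat:
        s = str(mat[taxon]).upper().replace("?", "N")
        seqs.append(Sequence(taxon.label, s))
    lengths = {len(s.seq) for s in seqs}
    bad = [n for n in lengths if n % 3 != 0]
    if bad:
        raise ValueError(f"{path}: alignment length {bad[0]} is not divisible by 3")
    aln = CodonAlignment.from_sequences(seqs, coding=False)
    tree = ds.tree_lists[0][0]
    return reconcile(aln, tree)


def write_nexus(aln: CodonAlignment, tree: dendropy.Tree, path) -> None:
    """Write an alignment plus embedded tree as a Nexus file."""
    taxa = dendropy.TaxonNamespace(aln.taxa)
    mat = dendropy.DnaCharacterMatrix.from_dict(
        {t: "".join(aln.rows[t]) for t in aln.taxa}, taxon_namespace=taxa
    )
    newick = tree.as_string(schema="newick").strip()
    with open(path, "w") as fh:
        fh.write(mat.as_string(schema="nexus"))
        fh.write("\nBEGIN TREES;\n    TREE timetree = %s\nEND;\n" % newick)


# ---------------------------------------------------------------------------
# Back-translation
# ---------------------------------------------------------------------------

def _coding_codons(taxon: str, cds: str, n_residues: int) -> list[str]:
    """Codons of a CDS expected to encode ``n_residues`` amino acids.

    A terminal stop codon is accepted and trimmed; internal stops and length
    mismatches are errors.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"{taxon}: CDS length {len(cds)} not divisible by 3")
    codons = split_codons(cds.upper())
    if len(codons) == n_residues + 1 and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if len(codons) != n_residues:
        raise ValueError(
            f"{taxon}: CDS has {len(codons)} codons but the ungapped protein row "
            f"has {n_residues} residues (terminal stop would also be accepted)"
        )
    return codons


def backtranslate_alignment(
    protein_msa: list[Sequence], cds_by_taxon: dict[str, str]
) -> CodonAlignment:
    """Reconstruct a codon alignment from a protein alignment and per-taxon CDS.

    Each amino-acid column maps to one codon column; protein gaps become the
    ``---`` gap codon. Per taxon the ungapped protein row must translate the
    CDS exactly under the standard genetic code (terminal stop accepted and
    trimmed); the first mismatch is reported with taxon, 1-based position and
    the expected/observed residues.
    """
    rows: dict[str, list[str]] = {}
    taxa = []
    for prot in protein_msa:
        if prot.id not in cds_by_taxon:
            raise ValueError(f"no CDS provided for taxon {prot.id!r}")
        residues = [a for a in prot.seq if a != "-"]
        codons = _coding_codons(prot.id, cds_by_taxon[prot.id], len(residues))
        for k, (aa, codon) in enumerate(zip(residues, codons)):
            observed = translate_codon(codon)
            if observed != aa.upper():
                raise ValueError(
                    f"{prot.id}: translation mismatch at protein position {k + 1}: "
                    f"alignment has {aa!r}, CDS codon {codon} encodes {observed!r}"
                )
        it = iter(codons)
        rows[prot.id] = [GAP_CODON if a == "-" else next(it) for a in prot.seq]
        taxa.append(prot.id)
    return CodonAlignment(taxa, rows, coding=False)


def dedupe_sequences(aln: CodonAlignment) -> CodonAlignment:
    """Collapse rows with identical full nucleotide strings.

    The first-in-input-order representative is kept; removed ids are logged.
    Idempotent.
    """
    seen: dict[str, str] = {}
    keep = []
    removed = []
    for t in aln.taxa:
        key = "".join(aln.rows[t])
        if key in seen:
            removed.append((t, seen[key]))
        else:
            seen[key] = t
            keep.append(t)
    if removed:
        logger.info(
            "dedupe: removed %d identical rows: %s",
            len(removed),
            ", ".join(f"{t} (= {rep})" for t, rep in removed),
        )
    return aln.subset(keep)
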