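"""miRNA seed-region extraction and 3'UTR matching.

The seed is the stretch of nucleotides near the miRNA 5' end that drives
target recognition.  Seeds are taken as windows starting at miRNA position 2
(1-based, i.e. skipping the first nucleotide) of lengths 6, 7 and 8 — the
canonical 6mer/7mer/8mer seed family anchored at position 2.  A candidate
binding site is an exact occurrence of the seed's reverse complement on the
mRNA sense strand (DNA alphabet) of the 3'UTR; no wobble pairing or mismatch
tolerance is allowed.

An associated gene::miRNA pair with a seed site is a candidate for *direct*
regulation; when the two fold changes point in opposite directions
(miRNA up, gene down or vice versa) the association is classified *inverse*,
the classical signature of repression by the miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "SeedMatchRecord",
    "extract_seeds",
    "reverse_complement_dna",
    "match_seed_to_utr",
    "classify_pair_direction",
    "annotate_associations",
]

_RNA = set("ACGU")
_DNA = set("ACGT")

SEED_LENGTHS = (6, 7, 8)
SEED_START = 1  # 0-based start of the seed window (canonical position 2)


@dataclass
class SeedMatchRecord:
    """One gene::miRNA::seed-length match against a 3'UTR."""

    mirna: str
    gene: str
    seed_length: int
    seed_sequence: str  # miRNA 5'->3', RNA alphabet
    site_positions: list[int]  # 0-based offsets into the UTR
    direction_class: str  # "concordant" or "inverse"
    direct_candidate: bool = True
    degenerate_direction: bool = False  # an FC of exactly 1 has no direction


def _check_alphabet(seq: str, alphabet: set[str], what: str) -> str:
    s = seq.upper()
    bad = set(s) - alphabet
    if bad:
        raise ValueError(f"{what} contains characters outside {sorted(alphabet)}: {sorted(bad)}")
    return s


def extract_seeds(mirna_sequence: str, start: int = SEED_START,
                  lengths: Sequence[int] = SEED_LENGTHS) -> list[tuple[int, str]]:
    """Return the seed windows of a mature miRNA as ``(length, seed)`` pairs.

    With the defaults this yields the windows covering miRNA positions 2-7,
    2-8 and 2-9 (1-based), so the 6-mer is a prefix of the 7-mer which is a
    prefix of the 8-mer.

    Raises
    ------
    ValueError
        If the sequence is shorter than ``start + max(lengths)`` or contains
        characters outside {A, C, G, U}.
    """
    seq = _check_alphabet(mirna_sequence, _RNA, "miRNA sequence")
    need = start + max(lengths)
    if len(seq) < need:
        raise ValueError(f"miRNA sequence of length {len(seq)} too short for seeds (need >= {need} nt)")
    return [(n, seq[start:start + n]) for n in lengths]


def reverse_complement_dna(seed: str) -> str:
    """Reverse-complement an RNA seed into the DNA string it would pair with.

    A->T, U->A, C->G, G->C, then reverse — i.e. the sense-strand DNA text a
    perfectly complementary site occupies in a 3'UTR.
    """
    seq = _check_alphabet(seed, _RNA, "seed")
    return str(Seq(seq).back_transcribe().reverse_complement())


def match_seed_to_utr(seed: str, utr: str) -> list[int]:
    """All (possibly overlapping) sites of a seed's reverse complement in a UTR.

    Returns 0-based offsets in ascending order; an empty UTR yields an empty
    list.
    """
    target = reverse_complement_dna(seed)
    text = _check_alphabet(utr, _DNA, "UTR") if utr else ""
    hits: list[int] = []
    pos = text.find(target)
    while pos != -1:
        hits.append(pos)
        pos = text.find(target, pos + 1)  # step 1 so overlapping sites count
    return hits


def classify_pair_direction(gene_fc: float, mirna_fc: float) -> tuple[str, bool]:
    """Classify a pair's fold changes as (direction_class, degenerate_flag).

    ``inverse`` iff exactly one of the two fold changes exceeds 1 and the
    other is below 1; otherwise ``concordant``.  A fold change of exactly 1
    has no direction, so such pairs are concordant with the degenerate flag
    set.
    """
    if gene_fc <= 0 or mirna_fc <= 0:
        raise ValueError("fold changes must be positive")
    if gene_fc == 1.0 or mirna_fc == 1.0:
        return "concordant", True
    inverse = (gene_fc > 1) != (mirna_fc > 1)
    return ("inverse" if inverse else "concordant"), False


def annotate_associations(
    associations: Iterable,
    mirna_sequences: Mapping[str, str],
    utr_sequences: Mapping[str, str],
) -> list[SeedMatchRecord]:
    """Scan every association's gene UTR for that miRNA's 6/7/8-nt seeds.

    Parameters
    ----------
    associations : iterable
        Objects with ``gene``, ``mirna``, ``gene_fc`` and ``mirna_fc``
        attributes (``AssociationResult``).
    mirna_sequences, utr_sequences : mapping
        id -> sequence.  Associations whose ids are missing a sequence are
        skipped (counted, not fatal).

    Returns
    -------
    list of SeedMatchRecord
        One record per (pair, seed length) with at least one site.
    """
    records: list[SeedMatchRecord] = []
    skipped = 0
    for assoc in associations:
        mseq = mirna_sequences.get(assoc.mirna)
        useq = utr_sequences.get(assoc.gene)
        if mseq is None or useq is None:
            skipped += 1
            continue
        direction, degenerate = classify_pair_direction(assoc.gene_fc, assoc.mirna_fc)
        for length, seed in extract_seeds(mseq):
            sites = match_seed_to_utr(seed, useq)
            if sites:
                records.append(SeedMatchRecord(
                    mirna=assoc.mirna, gene=assoc.gene, seed_length=length,
                    seed_sequence=seed, site_positions=sites,
                    direction_class=direction, direct_candidate=True,
                    degenerate_direction=degenerate,
                ))
    if skipped:
        import logging
        logging.getLogger(__name__).warning("annotate_associations: %d associations skipped for missing sequences", skipped)
    return records
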