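"""Standard genetic code tables used throughout the package.

Derived from Biopython's standard codon table (NCBI table 1) so the code
itself is never hand-typed. The package works with three codon universes:

* 61 sense codons (all non-stop codons),
* 59 synonymous sense codons (Met/ATG and Trp/TGG excluded, because a
  single-codon amino acid carries no synonymous-usage information),
* per-amino-acid codon families for RSCU and isoacceptor partitioning.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_STD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STD.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of codons, sorted
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

#: amino acids encoded by a single codon; carry no synonymous signal
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, codons in AA_TO_CODONS.items() if len(codons) == 1
)  # {M, W}

#: the 18 amino acids with >= 2 synonymous codons
DEGENERATE_AAS: frozenset[str] = frozenset(AA_TO_CODONS) - SINGLE_CODON_AAS

#: 59 codons belonging to degenerate amino acids (the RSCU universe)
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] in DEGENERATE_AAS
)

#: codon degeneracy n_x of the amino acid each codon encodes
CODON_DEGENERACY: dict[str, int] = {
    c: len(AA_TO_CODONS[CODON_TO_AA[c]]) for c in SENSE_CODONS
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
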