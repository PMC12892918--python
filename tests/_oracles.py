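"""Independent brute-force oracles used only by the test suite.

Deliberately naive re-derivations (explicit codon dictionary, character-wise
reverse complement, window enumeration, substring scans) kept separate from
the library code paths they check.
"""
from __future__ import annotations

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[i * 16 + j * 4 + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def oracle_translate(seq: str, offset: int = 0) -> str:
    """Codon-by-codon translation from offset to the first stop codon."""
    out = []
    for i in range(offset, len(seq) - 2, 3):
        aa = CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def oracle_splice(chrom_seq: str, exons, strand: str) -> str:
    """Concatenate exon slices in genomic order; reverse-complement on minus."""
    s = "".join(chrom_seq[a:b] for a, b in exons)
    return oracle_revcomp(s) if strand == "-" else s


def oracle_psi(ijc: int, sjc: int, inc_len: int, skip_len: int):
    """Length normalisation spelled out step by step."""
    if ijc == 0 and sjc == 0:
        return None
    inc_density = ijc / inc_len
    skip_density = sjc / skip_len
    return inc_density / (inc_density + skip_density)


def oracle_windows(protein: str, lo: int, hi: int, kmin: int, kmax: int) -> set[str]:
    """All k-mers of protein overlapping residue interval [lo, hi) by >= 1."""
    out = set()
    for k in range(kmin, kmax + 1):
        for start in range(len(protein) - k + 1):
            if start + k > lo and start < hi:
                out.add(protein[start : start + k])
    return out


def oracle_substring_hits(kmers, proteome: dict[str, str]) -> set[str]:
    """Naive scan: which k-mers occur in any proteome sequence."""
    hits = set()
    for pep in kmers:
        for seq in proteome.values():
            if pep in seq:
                hits.add(pep)
                break
    return hits
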