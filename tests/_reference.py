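"""Naive pure-Python reference implementations used only as test oracles.

Deliberately written with plain string operations and explicit loops,
sharing no code with the package's vectorized paths. Only suitable for
tiny inputs.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def pam_ok(window: str, pam: str) -> bool:
    return all(b != "N" and b in IUPAC[p] for b, p in zip(window, pam))


def naive_enumerate(contigs: list[tuple[str, str]], k: int = 25, pam: str = "TTTV"):
    """All (contig, start, strand, sequence) PAM-anchored N-free windows."""
    out = []
    for name, seq in contigs:
        for start in range(len(seq) - k + 1):
            w = seq[start : start + k]
            if "N" in w:
                continue
            if pam_ok(w, pam):
                out.append((name, start, "+", w))
            rc = revcomp(w)
            if pam_ok(rc, pam):
                out.append((name, start, "-", rc))
    return out


def naive_offtargets(
    protospacer: str,
    contigs: list[tuple[str, str]],
    max_mm: int,
    require_pam: bool = True,
    pam: str = "TTTV",
    pam_len: int = 4,
):
    """All (contig, start, strand, mismatches) windows whose post-PAM
    segment is within max_mm of the protospacer."""
    k = pam_len + len(protospacer)
    out = []
    for name, seq in contigs:
        for start in range(len(seq) - k + 1):
            for strand in "+-":
                w = seq[start : start + k] if strand == "+" else revcomp(seq[start : start + k])
                if "N" in w:
                    continue
                if require_pam and not pam_ok(w, pam):
                    continue
                mm = sum(1 for a, b in zip(w[pam_len:], protospacer) if a != b)
                if mm <= max_mm:
                    out.append((name, start, strand, mm))
    return out
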