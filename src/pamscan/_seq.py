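"""Low-level sequence machinery shared across the package.

Sequences are plain Python strings over {A,C,G,T,N}; hot loops work on
numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4). ``N`` never matches
anything: a window containing N is excluded from enumeration and from
off-target candidacy at every distance.
"""

from __future__ import annotations

import numpy as np

#: byte -> base code lookup; 255 flags an illegal residue
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC one-letter ambiguity codes -> the set of concrete bases matched
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase A/C/G/T/N string as a uint8 code array."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        pos = int(np.argmax(arr == 255))
        raise ValueError(f"illegal residue {seq[pos]!r} at position {pos}")
    return arr


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def pam_match_tables(pam: str) -> list[np.ndarray]:
    """One boolean lookup table (length 5, indexed by base code) per PAM
    position. The N code (4) is always False: an N in the genome never
    satisfies a PAM position, even pattern letter N."""
    tables = []
    for letter in pam.upper():
        try:
            allowed = IUPAC_SETS[letter]
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {letter!r} in PAM pattern {pam!r}") from None
        t = np.zeros(5, dtype=bool)
        for b in allowed:
            t[_CODE[ord(b)]] = True
        tables.append(t)
    return tables


def window_has_n(enc: np.ndarray, k: int) -> np.ndarray:
    """Boolean array over window starts 0..L-k: True where the k-window
    contains at least one N."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    cs = np.concatenate(([0], np.cumsum(enc == 4, dtype=np.int64)))
    return (cs[k:] - cs[:-k]) > 0


def find_pam_sites(enc: np.ndarray, k: int, pam_tables: list[np.ndarray]) -> np.ndarray:
    """Start positions of k-windows whose prefix matches the PAM tables and
    which contain no N."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j, table in enumerate(pam_tables):
        ok &= table[enc[j : j + n]]
    ok &= ~window_has_n(enc, k)
    return np.flatnonzero(ok).astype(np.int64)


def matches_pam(seq: str, pam: str) -> bool:
    """Does ``seq`` begin with the IUPAC PAM pattern (N in seq never matches)?"""
    if len(seq) < len(pam):
        return False
    for s, p in zip(seq, pam.upper()):
        if s == "N" or s not in IUPAC_SETS[p]:
            return False
    return True


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best
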