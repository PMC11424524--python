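"""Pairwise alignment of near-identical sequences.

Thin wrapper around edlib (adaptive-banded, globally optimal unit-cost edit
distance). IUPAC ambiguity codes are scored as matches against any
compatible symbol (intersecting base sets), so an assembly's Y aligned over
the reference's T costs nothing during alignment — difference accounting
happens downstream on the gapped strings, not in the alignment score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations

import edlib

from ._seq import IUPAC_TO_SET
from .errors import BandExceededError

#: pairs of distinct IUPAC symbols whose base sets intersect
IUPAC_EQUALITIES: list[tuple[str, str]] = [
    (x, y)
    for x, y in combinations(IUPAC_TO_SET, 2)
    if IUPAC_TO_SET[x] & IUPAC_TO_SET[y]
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two equal-length gapped strings.

    No column carries a gap in both sequences.
    """

    gapped_a: str
    gapped_b: str
    edit_distance: int

    @property
    def columns(self) -> int:
        return len(self.gapped_a)


def expand_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def gapped_from_cigar(query: str, target: str, cigar: str,
                      t_start: int = 0) -> tuple[str, str]:
    """Gapped (query, target) strings from an edlib extended cigar.

    'I' consumes query only (gap in target); 'D' consumes target only.
    """
    ga, gb = [], []
    qi, ti = 0, t_start
    for n, op in expand_cigar(cigar):
        if op in "=XM":
            ga.append(query[qi : qi + n])
            gb.append(target[ti : ti + n])
            qi += n
            ti += n
        elif op == "I":
            ga.append(query[qi : qi + n])
            gb.append("-" * n)
            qi += n
        else:  # D
            ga.append("-" * n)
            gb.append(target[ti : ti + n])
            ti += n
    return "".join(ga), "".join(gb)


def global_align(a: str, b: str, band: int | None = None) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch-style) alignment under unit edit costs.

    ``band`` caps the edit distance explored (edlib's k); exceeding it raises
    BandExceededError with a suggested wider band. ``band=None`` explores
    until the optimum is found.
    """
    k = -1 if band is None else band
    res = edlib.align(a, b, mode="NW", task="path", k=k,
                      additionalEqualities=IUPAC_EQUALITIES)
    if res["editDistance"] < 0:
        raise BandExceededError(band)
    ga, gb = gapped_from_cigar(a, b, res["cigar"])
    return PairwiseAlignment(gapped_a=ga, gapped_b=gb,
                             edit_distance=res["editDistance"])


def infix_align(query: str, target: str) -> tuple[int, int, int, str]:
    """Optimal infix (query-global, target-local) alignment.

    Returns (edit_distance, target_start, target_end, cigar); gaps at the
    target's ends are free.
    """
    res = edlib.align(query, target, mode="HW", task="path",
                      additionalEqualities=IUPAC_EQUALITIES)
    t_start, t_end = res["locations"][0]
    return res["editDistance"], t_start, t_end + 1, res["cigar"]
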