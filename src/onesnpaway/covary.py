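"""Complementary-charge covariation between partner-protein segments.

Given aligned C-terminal segments of two interacting proteins (e.g. an
i-spanin and its o-spanin) across a family of homologs, score every column
pair for charge complementarity: a homolog *supports* a pair when the two
columns carry opposite charges (one positive, one negative) or are jointly
non-charged; the score is the supporting fraction. A pair is flagged
*variable* only when both columns take at least two charge classes across
the family — without variation, complementarity carries no covariation
signal. This complementarity-state score is this tool's own definition (the
analysis it generalizes reported a single observed pair, not a formula).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

GAP = "-"

POSITIVE = "positive"
NEGATIVE = "negative"
POLAR = "polar"
OTHER = "other"

#: Residue -> charge class. D/E negative; K/R positive; H/S/T/N/Q/Y polar;
#: the remaining residues and the gap symbol are "other".
CHARGE_CLASSES: Mapping[str, str] = {
    **{aa: NEGATIVE for aa in "DE"},
    **{aa: POSITIVE for aa in "KR"},
    **{aa: POLAR for aa in "HSTNQY"},
    **{aa: OTHER for aa in "ACFGILMPVW"},
    GAP: OTHER,
}


def charge_class(residue: str) -> str:
    """Charge class of a one-letter residue (or the gap symbol)."""
    try:
        return CHARGE_CLASSES[residue.upper() if residue != GAP else GAP]
    except KeyError:
        raise ValueError(f"unknown residue symbol {residue!r}") from None


@dataclass(frozen=True)
class Homolog:
    label: str
    segment_a: str
    segment_b: str


@dataclass(frozen=True)
class AlignedPairFamily:
    """Aligned segment pairs across >=2 homologs; columns are 1-based."""

    homologs: tuple[Homolog, ...]

    def __post_init__(self) -> None:
        if len(self.homologs) < 2:
            raise ValueError("a family needs at least 2 homologs")
        len_a = {len(h.segment_a) for h in self.homologs}
        len_b = {len(h.segment_b) for h in self.homologs}
        if len(len_a) != 1 or len(len_b) != 1:
            raise ValueError("aligned segments must all have equal length per partner")
        for h in self.homologs:
            for seg in (h.segment_a, h.segment_b):
                for r in seg:
                    charge_class(r)  # raises on unknown symbols

    @property
    def len_a(self) -> int:
        return len(self.homologs[0].segment_a)

    @property
    def len_b(self) -> int:
        return len(self.homologs[0].segment_b)

    def column_a(self, col: int) -> str:
        self._check_col(col, self.len_a, "A")
        return "".join(h.segment_a[col - 1] for h in self.homologs)

    def column_b(self, col: int) -> str:
        self._check_col(col, self.len_b, "B")
        return "".join(h.segment_b[col - 1] for h in self.homologs)

    @staticmethod
    def _check_col(col: int, length: int, partner: str) -> None:
        if not 1 <= col <= length:
            raise IndexError(f"column {col} out of range 1..{length} in segment {partner}")

    def swapped(self) -> "AlignedPairFamily":
        return AlignedPairFamily(
            tuple(Homolog(h.label, h.segment_b, h.segment_a) for h in self.homologs)
        )


@dataclass(frozen=True)
class CovarianceHit:
    """A scored column pair; ``score`` is the supporting fraction in [0, 1]."""

    column_a: int
    column_b: int
    score: float
    variable: bool
    n_support: int
    n_total: int


def _supports(class_a: str, class_b: str) -> bool:
    charged = {POSITIVE, NEGATIVE}
    if class_a in charged and class_b in charged:
        return class_a != class_b  # opposite charges
    return class_a not in charged and class_b not in charged  # jointly non-charged


def _score_columns(col_a: str, col_b: str) -> tuple[float, bool, int, int]:
    pairs = [
        (charge_class(a), charge_class(b))
        for a, b in zip(col_a, col_b)
        if a != GAP and b != GAP  # gapped homologs leave the denominator
    ]
    if not pairs:
        return 0.0, False, 0, 0
    support = sum(_supports(ca, cb) for ca, cb in pairs)
    classes_a = {ca for ca, _ in pairs}
    classes_b = {cb for _, cb in pairs}
    variable = len(classes_a) >= 2 and len(classes_b) >= 2
    return support / len(pairs), variable, support, len(pairs)


def score_column_pair(family: AlignedPairFamily, column_a: int, column_b: int) -> CovarianceHit:
    """Complementarity score of one (segment-A column, segment-B column) pair."""
    score, variable, n_support, n_total = _score_columns(
        family.column_a(column_a), family.column_b(column_b)
    )
    return CovarianceHit(column_a, column_b, score, variable, n_support, n_total)


def scan_all_pairs(
    family: AlignedPairFamily, min_variability: bool = False
) -> list[CovarianceHit]:
    """Score every column pair, ranked best first.

    Ranking: variable pairs first, then by score, then by proximity to the
    C-terminus of both segments (the biologically expected interaction end),
    then by column indices for byte-for-byte determinism. With
    ``min_variability`` only variable pairs are returned.
    """
    hits = [
        score_column_pair(family, a, b)
        for a in range(1, family.len_a + 1)
        for b in range(1, family.len_b + 1)
    ]
    if min_variability:
        hits = [h for h in hits if h.variable]
    hits.sort(
        key=lambda h: (
            not h.variable,
            -h.score,
            (family.len_a - h.column_a) + (family.len_b - h.column_b),
            h.column_a,
            h.column_b,
        )
    )
    return hits


def permutation_null(
    family: AlignedPairFamily,
    column_a: int,
    column_b: int,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null score distribution: homolog labels of partner B shuffled.

    Shuffling one partner's rows breaks any genuine inter-partner linkage
    while preserving both column compositions.
    """
    rng = np.random.default_rng(seed)
    col_a = family.column_a(column_a)
    col_b = family.column_b(column_b)
    n = len(col_a)
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        perm = rng.permutation(n)
        shuffled_b = "".join(col_b[i] for i in perm)
        scores[k], _, _, _ = _score_columns(col_a, shuffled_b)
    return scores


def hits_to_tsv(hits: Sequence[CovarianceHit], header_comment: str | None = None) -> str:
    """TSV: column_a, column_b, score, variable, n_support."""
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    buf.write("column_a\tcolumn_b\tscore\tvariable\tn_support\n")
    for h in hits:
        buf.write(f"{h.column_a}\t{h.column_b}\t{h.score:.4f}\t{int(h.variable)}\t{h.n_support}\n")
    return buf.getvalue()
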