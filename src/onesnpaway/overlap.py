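"""Embedded (overlapping-frame) gene architectures.

Models a gene whose open reading frame lies entirely inside another gene's
coding sequence but in a shifted frame on the same strand — the arrangement
of phage lambda *Rz1*, which sits in the +1 frame of *Rz*. Because any two
overlapping codons share at most two nucleotides, a single substitution
touches exactly one codon in each frame, and its joint consequence can be
computed and, conversely, *designed*: e.g. "a nonsense change in the parent
that is synonymous in the embedded gene".

``embed_codon_count`` counts all codons of the embedded ORF *including* its
terminal stop; ``OverlapArchitecture.sense_codon_count`` gives the
protein-coding codon number (60 for lambda Rz1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable

from .seqcore import (
    CodingSequence,
    GeneticCode,
    PointSubstitution,
    SubstitutionEffect,
    all_substitutions,
    apply_substitution,
    standard_code,
    EFFECT_NONSENSE,
    EFFECT_SYNONYMOUS,
    STOP,
)

#: Sentinel for a substitution that does not touch the embedded ORF.
OUTSIDE = "OUTSIDE"


@dataclass(frozen=True)
class OverlapArchitecture:
    """An embedded ORF at ``embed_nt_offset`` (0-based) within ``parent``.

    The frame shift is ``embed_nt_offset % 3`` and must be +1 or +2; the
    embedded span must start with ATG, end with a stop codon, contain no
    internal stop in its own frame, and lie entirely within the parent.
    """

    parent: CodingSequence
    embed_nt_offset: int
    embed_codon_count: int
    embed_id: str = ""

    def __post_init__(self) -> None:
        if self.frame_shift not in (1, 2):
            raise ValueError(
                f"embedded offset {self.embed_nt_offset} is in-frame with the parent "
                "(frame shift must be +1 or +2)"
            )
        if self.embed_codon_count < 2:
            raise ValueError("embedded ORF needs at least a start and a stop codon")
        if self.embed_nt_offset < 0 or self.embed_end > len(self.parent.nt):
            raise ValueError("embedded ORF extends outside the parent CDS")
        embedded = self.embedded_cds()  # validates ATG/stop/internal-stop invariants
        if not embedded.nt.startswith("ATG"):
            raise ValueError("embedded ORF does not start with ATG")

    @property
    def frame_shift(self) -> int:
        return self.embed_nt_offset % 3

    @property
    def embed_end(self) -> int:
        """0-based exclusive end of the embedded span in parent coordinates."""
        return self.embed_nt_offset + 3 * self.embed_codon_count

    @property
    def sense_codon_count(self) -> int:
        return self.embed_codon_count - 1

    def embedded_cds(self, code: GeneticCode | None = None) -> CodingSequence:
        nt = self.parent.nt[self.embed_nt_offset : self.embed_end]
        cds = CodingSequence(
            id=self.embed_id or f"{self.parent.id}|embedded@{self.embed_nt_offset}",
            nt=nt,
            includes_terminal_stop=True,
        )
        if code is not None:
            cds.validate(code)
        return cds

    def contains_nt(self, nt_index0: int) -> bool:
        return self.embed_nt_offset <= nt_index0 < self.embed_end

    def to_embedded_coords(self, nt_index0: int) -> tuple[int, int]:
        """Map a 0-based parent nt index to (embedded codon index, offset)."""
        rel = nt_index0 - self.embed_nt_offset
        if rel < 0 or nt_index0 >= self.embed_end:
            raise ValueError(f"nt position {nt_index0} outside the embedded span")
        return rel // 3 + 1, rel % 3 + 1


@dataclass(frozen=True)
class DualFrameEffect:
    """A substitution's joint consequence in the parent and embedded frames.

    ``embedded_effect`` is :data:`OUTSIDE` when the changed nucleotide falls
    outside the embedded span; ``embedded_codon_index`` is then ``None``.
    """

    substitution: PointSubstitution
    parent_effect: SubstitutionEffect
    embedded_effect: SubstitutionEffect | str
    embedded_codon_index: int | None = None

    @property
    def outside_embedded(self) -> bool:
        return isinstance(self.embedded_effect, str) and self.embedded_effect == OUTSIDE


def locate_embedded_orf(
    parent: CodingSequence,
    frame_shift: int | None = None,
    code: GeneticCode | None = None,
    min_codons: int = 2,
) -> list[OverlapArchitecture]:
    """All ATG→stop ORFs in the shifted frame(s), entirely inside ``parent``.

    Candidates are sorted by decreasing codon count, ties broken by smaller
    offset. ``frame_shift`` of +1 or +2 restricts the search to one frame;
    ``None`` searches both. Nested ATGs sharing a stop yield one candidate
    each.
    """
    code = code or standard_code()
    if frame_shift not in (None, 1, 2):
        raise ValueError(f"frame_shift must be +1, +2 or None, got {frame_shift}")
    shifts = (1, 2) if frame_shift is None else (frame_shift,)
    nt = parent.nt
    out: list[OverlapArchitecture] = []
    for shift in shifts:
        for off in range(shift, len(nt) - 2, 3):
            if nt[off : off + 3] != "ATG":
                continue
            j = off
            while j + 3 <= len(nt):
                codon = nt[j : j + 3]
                if code.is_stop(codon):
                    n_codons = (j + 3 - off) // 3
                    if n_codons >= min_codons:
                        out.append(
                            OverlapArchitecture(
                                parent=parent,
                                embed_nt_offset=off,
                                embed_codon_count=n_codons,
                            )
                        )
                    break
                j += 3
    out.sort(key=lambda a: (-a.embed_codon_count, a.embed_nt_offset))
    return out


@lru_cache(maxsize=64)
def _embedded_cds_cached(arch: OverlapArchitecture) -> CodingSequence:
    return arch.embedded_cds()


def dual_frame_effect(
    arch: OverlapArchitecture,
    sub: PointSubstitution,
    code: GeneticCode | None = None,
) -> DualFrameEffect:
    """Compute a substitution's effect in both frames (parent coordinates)."""
    code = code or standard_code()
    parent_effect = apply_substitution(arch.parent, sub, code)
    p = sub.nt_index0
    if not arch.contains_nt(p):
        return DualFrameEffect(sub, parent_effect, OUTSIDE, None)
    emb_idx, emb_off = arch.to_embedded_coords(p)
    embedded = _embedded_cds_cached(arch)
    emb_sub = sub.shift(emb_idx, emb_off)
    embedded_effect = apply_substitution(embedded, emb_sub, code)
    return DualFrameEffect(sub, parent_effect, embedded_effect, emb_idx)


EffectPredicate = Callable[[SubstitutionEffect], bool]


def effect_is(effect_class: str, stop_name: str | None = None) -> EffectPredicate:
    """Predicate factory: effect has the given class (and stop name, if set)."""

    def pred(e: SubstitutionEffect) -> bool:
        if e.effect_class != effect_class:
            return False
        return stop_name is None or e.stop_name == stop_name

    return pred


is_synonymous: EffectPredicate = effect_is(EFFECT_SYNONYMOUS)
is_nonsense: EffectPredicate = effect_is(EFFECT_NONSENSE)


def design_constrained(
    arch: OverlapArchitecture,
    want_parent: EffectPredicate,
    want_embedded: EffectPredicate | None,
    codon_range: tuple[int, int] | None = None,
    code: GeneticCode | None = None,
    allow_outside: bool = False,
) -> list[DualFrameEffect]:
    """Exhaustive search for substitutions satisfying both frame constraints.

    Every single-nucleotide substitution over the parent's sense codons in
    ``codon_range`` (1-based inclusive; default: all) is classified in both
    frames and kept iff ``want_parent(parent_effect)`` holds and the embedded
    side satisfies ``want_embedded`` — substitutions outside the embedded
    span pass the embedded constraint only when ``allow_outside`` (or when
    ``want_embedded`` is ``None``, which ignores the embedded frame entirely).
    Unsatisfiable constraints return an empty list. Results are sorted by
    (codon_index, offset, alt_base).
    """
    code = code or standard_code()
    last = arch.parent.sense_codon_count
    lo, hi = codon_range if codon_range is not None else (1, last)
    if not (1 <= lo <= hi <= last):
        raise ValueError(f"design range {lo}..{hi} outside sense codons 1..{last}")
    out = []
    for sub in all_substitutions(arch.parent):
        if not lo <= sub.codon_index <= hi:
            continue
        dfe = dual_frame_effect(arch, sub, code)
        if not want_parent(dfe.parent_effect):
            continue
        if want_embedded is not None:
            if dfe.outside_embedded:
                if not allow_outside:
                    continue
            elif not want_embedded(dfe.embedded_effect):
                continue
        out.append(dfe)
    out.sort(
        key=lambda d: (d.substitution.codon_index, d.substitution.offset, d.substitution.alt_base)
    )
    return out


def designs_to_tsv(designs: Iterable[DualFrameEffect], header_comment: str | None = None) -> str:
    """TSV: parent_codon, offset, ref>alt, parent_effect, embedded_codon, embedded_effect, stop_name."""
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    buf.write(
        "parent_codon\toffset\tchange\tparent_effect\tembedded_codon\tembedded_effect\tstop_name\n"
    )
    for d in designs:
        s = d.substitution
        if d.outside_embedded:
            emb_codon, emb_eff = "", OUTSIDE
        else:
            emb_codon = str(d.embedded_codon_index)
            emb_eff = d.embedded_effect.effect_class
        stop_name = d.parent_effect.stop_name
        if stop_name == "none" and not d.outside_embedded:
            stop_name = d.embedded_effect.stop_name
        buf.write(
            f"{s.codon_index}\t{s.offset}\t{s.ref_base}>{s.alt_base}\t"
            f"{d.parent_effect.effect_class}\t{emb_codon}\t{emb_eff}\t{stop_name}\n"
        )
    return buf.getvalue()
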