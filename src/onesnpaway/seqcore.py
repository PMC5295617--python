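"""Genetic-code primitives.

Codons, translation, single-nucleotide codon neighborhoods, and the
classification of one-base substitutions (synonymous / missense / nonsense /
start-loss / stop-loss; transition vs. transversion; amber / ochre / opal
stop naming).

Conventions used throughout the package:

* Codon and protein coordinates are 1-based; codon ``i`` of a coding
  sequence covers nucleotides ``3i-2 .. 3i`` (1-based, inclusive), and
  protein position ``i`` corresponds to codon ``i``.
* Residue intervals are inclusive on both ends.
* Only the unambiguous alphabet ``{A, C, G, T}`` is accepted. Ambiguity
  codes are rejected rather than skipped, so every reported count is exact.
* The terminal stop codon of a CDS is stored but excluded from translation
  output and from scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Mapping

from Bio.Data import CodonTable

NUCLEOTIDES = ("A", "C", "G", "T")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: Sentinel amino-acid symbol for a stop codon.
STOP = "*"

#: Conventional names of the three standard stop codons.
STOP_NAMES: Mapping[str, str] = {"TAG": "amber", "TAA": "ochre", "TGA": "opal"}

TRANSITION = "transition"
TRANSVERSION = "transversion"

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_MISSENSE = "missense"
EFFECT_NONSENSE = "nonsense"
EFFECT_STOP_LOSS = "stop_loss"
EFFECT_START_LOSS = "start_loss"


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise ValueError(f"invalid codon {codon!r}: expected a 3-mer over A/C/G/T")
    return codon


@dataclass(frozen=True)
class GeneticCode:
    """A codon table mapping each of the 64 codons to an amino acid or stop.

    Stops are represented by :data:`STOP` (``"*"``). ``start_codons`` are the
    initiation codons of the table (used to classify start-loss changes).
    """

    table: Mapping[str, str]
    name: str = "standard"
    start_codons: frozenset[str] = frozenset({"ATG"})

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 entries, got {len(self.table)}")
        for codon, aa in self.table.items():
            _check_codon(codon)
            if not (aa == STOP or (len(aa) == 1 and aa.isalpha() and aa.isupper())):
                raise ValueError(f"bad amino-acid symbol {aa!r} for codon {codon}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi_table("Standard")

    @classmethod
    def from_ncbi_table(cls, name_or_id) -> "GeneticCode":
        """Build a :class:`GeneticCode` from an NCBI codon table (via Biopython)."""
        if isinstance(name_or_id, int):
            bio = CodonTable.unambiguous_dna_by_id[name_or_id]
        else:
            bio = CodonTable.unambiguous_dna_by_name[name_or_id]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = STOP
        label = "standard" if bio.id == 1 else (bio.names[0] if bio.names else str(bio.id))
        return cls(table=table, name=label, start_codons=frozenset(bio.start_codons))

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid for ``codon``, or ``"*"`` for a stop."""
        return self.table[_check_codon(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.table[_check_codon(codon)] == STOP

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == STOP)

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa != STOP)

    def codons_for(self, target: str) -> frozenset[str]:
        """All codons encoding amino acid ``target`` (or all stops for ``"*"``)."""
        target = normalize_target(target)
        hits = frozenset(c for c, aa in self.table.items() if aa == target)
        if not hits:
            raise ValueError(f"no codon encodes {target!r} in code {self.name!r}")
        return hits


@lru_cache(maxsize=None)
def _standard() -> GeneticCode:
    return GeneticCode.standard()


def standard_code() -> GeneticCode:
    """The standard genetic code (cached singleton)."""
    return _standard()


def normalize_target(target: str) -> str:
    """Normalize a scan target: an upper-case amino-acid letter or ``"*"``.

    Accepts ``"*"``, ``"STOP"``, ``"stop"``, ``"X"`` for stop targets.
    """
    if not isinstance(target, str) or not target:
        raise ValueError(f"invalid target {target!r}")
    if target in (STOP, "X") or target.upper() == "STOP":
        return STOP
    t = target.upper()
    if len(t) == 1 and t in "ACDEFGHIKLMNPQRSTVWY":
        return t
    raise ValueError(f"invalid target {target!r}: expected an amino-acid letter or STOP")


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame nucleotide sequence.

    ``nt`` must be over A/C/G/T with length divisible by 3 and must not
    contain an internal stop codon. If ``includes_terminal_stop`` the last
    codon must be a stop; the stop is stored but never translated or scanned.
    """

    id: str
    nt: str
    includes_terminal_stop: bool = field(default=True)

    def __post_init__(self) -> None:
        nt = self.nt.upper()
        object.__setattr__(self, "nt", nt)
        if len(nt) == 0 or len(nt) % 3:
            raise ValueError(f"{self.id}: CDS length {len(nt)} not divisible by 3")
        bad = sorted({b for b in nt if b not in NUCLEOTIDES})
        if bad:
            raise ValueError(f"{self.id}: non-ACGT symbol(s) {''.join(bad)} in sequence")
        code = standard_code()
        # The internal-stop / terminal-stop invariants are checked against the
        # standard code at construction; validate(code) re-checks for others.
        self._validate_stops(code)

    def _validate_stops(self, code: GeneticCode) -> None:
        n = self.codon_count
        for i in range(1, n + 1):
            codon = self.codon(i)
            if code.is_stop(codon):
                if self.includes_terminal_stop and i == n:
                    return
                raise ValueError(f"{self.id}: internal stop codon {codon} at codon {i}")
        if self.includes_terminal_stop:
            raise ValueError(f"{self.id}: terminal codon {self.codon(n)} is not a stop")

    def validate(self, code: GeneticCode) -> "CodingSequence":
        """Re-check the stop invariants under a non-standard code."""
        self._validate_stops(code)
        return self

    @property
    def codon_count(self) -> int:
        """Total number of codons, including the terminal stop if present."""
        return len(self.nt) // 3

    @property
    def sense_codon_count(self) -> int:
        return self.codon_count - (1 if self.includes_terminal_stop else 0)

    def codon(self, i: int) -> str:
        """Codon ``i`` (1-based)."""
        if not 1 <= i <= self.codon_count:
            raise IndexError(f"{self.id}: codon index {i} out of range 1..{self.codon_count}")
        return self.nt[3 * (i - 1) : 3 * i]

    def codons(self, include_stop: bool = False) -> Iterator[tuple[int, str]]:
        last = self.codon_count if include_stop else self.sense_codon_count
        for i in range(1, last + 1):
            yield i, self.codon(i)

    def with_substitution(self, sub: "PointSubstitution") -> "CodingSequence":
        """Return a new (unvalidated-as-CDS) raw mutant nucleotide string.

        The mutant may contain a premature stop, so it is returned as a plain
        string rather than a :class:`CodingSequence`.
        """
        raise NotImplementedError("use mutate_nt() which returns the raw string")

    def mutate_nt(self, sub: "PointSubstitution") -> str:
        """Apply ``sub`` to the raw nucleotide string (after consistency checks)."""
        sub.check_against(self)
        p = sub.nt_index0
        return self.nt[:p] + sub.alt_base + self.nt[p + 1 :]


@dataclass(frozen=True)
class PointSubstitution:
    """One nucleotide change at offset 1..3 of a 1-based codon index."""

    codon_index: int
    offset: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.offset not in (1, 2, 3):
            raise ValueError(f"offset {self.offset} not in 1..3")
        for b in (self.ref_base, self.alt_base):
            if b not in NUCLEOTIDES:
                raise ValueError(f"invalid base {b!r}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt base are both {self.ref_base!r}")
        if self.codon_index < 1:
            raise ValueError(f"codon index {self.codon_index} must be >= 1")

    @property
    def nt_index0(self) -> int:
        """0-based position in the nucleotide string."""
        return 3 * (self.codon_index - 1) + self.offset - 1

    @property
    def nt_position(self) -> int:
        """1-based position in the nucleotide string."""
        return self.nt_index0 + 1

    def check_against(self, cds: CodingSequence) -> None:
        if self.codon_index > cds.codon_count:
            raise IndexError(
                f"{cds.id}: codon index {self.codon_index} out of range 1..{cds.codon_count}"
            )
        actual = cds.nt[self.nt_index0]
        if actual != self.ref_base:
            raise ValueError(
                f"{cds.id}: ref base mismatch at codon {self.codon_index} offset "
                f"{self.offset}: sequence has {actual}, substitution expects {self.ref_base}"
            )

    def shift(self, new_codon_index: int, new_offset: int) -> "PointSubstitution":
        return PointSubstitution(new_codon_index, new_offset, self.ref_base, self.alt_base)

    def __str__(self) -> str:  # e.g. "100:1:C>T"
        return f"{self.codon_index}:{self.offset}:{self.ref_base}>{self.alt_base}"

    @classmethod
    def parse(cls, literal: str) -> "PointSubstitution":
        """Parse the ``CODON:OFFSET:REF>ALT`` literal (e.g. ``100:1:C>T``)."""
        try:
            idx, off, change = literal.split(":")
            ref, alt = change.split(">")
            return cls(int(idx), int(off), ref.upper(), alt.upper())
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"malformed substitution literal {literal!r}; "
                             "expected CODON:OFFSET:REF>ALT, e.g. 100:1:C>T") from exc


@dataclass(frozen=True)
class SubstitutionEffect:
    """Codon-level consequence of one nucleotide substitution.

    ``effect_class`` is one of synonymous / missense / nonsense / stop_loss /
    start_loss. A start-loss at codon 1 that also changes the encoded residue
    (e.g. Met1Lys) keeps ``counts_as_missense`` true so mutant-table summaries
    can treat it as a missense change.
    """

    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: str
    mutation_type: str
    stop_name: str = "none"
    counts_as_missense: bool = False

    @property
    def is_nonsense(self) -> bool:
        return self.effect_class == EFFECT_NONSENSE


def translate(cds: CodingSequence, code: GeneticCode | None = None) -> str:
    """Translate a CDS; the terminal stop (if stored) is not emitted.

    Raises ``ValueError`` naming the codon index on an internal stop.
    """
    code = code or standard_code()
    out = []
    for i, codon in cds.codons(include_stop=False):
        aa = code.amino_acid(codon)
        if aa == STOP:
            raise ValueError(f"{cds.id}: internal stop codon {codon} at codon {i}")
        out.append(aa)
    return "".join(out)


def codon_neighbors(codon: str) -> set[str]:
    """The 9 codons at Hamming distance exactly 1 from ``codon``."""
    _check_codon(codon)
    out = set()
    for off in range(3):
        for b in NUCLEOTIDES:
            if b != codon[off]:
                out.add(codon[:off] + b + codon[off + 1 :])
    return out


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """``"transition"`` if both bases are purines or both pyrimidines."""
    for b in (ref_base, alt_base):
        if b not in NUCLEOTIDES:
            raise ValueError(f"invalid base {b!r}")
    if ref_base == alt_base:
        raise ValueError(f"not a substitution: {ref_base}>{alt_base}")
    same_class = {ref_base, alt_base} <= PURINES or {ref_base, alt_base} <= PYRIMIDINES
    return TRANSITION if same_class else TRANSVERSION


def classify_effect(
    ref_codon: str,
    alt_codon: str,
    code: GeneticCode,
    at_start_codon: bool = False,
) -> tuple[str, str, str, bool]:
    """Classify ref->alt codon change: (ref_aa, alt_aa, effect_class, counts_as_missense)."""
    ref_aa = code.amino_acid(ref_codon)
    alt_aa = code.amino_acid(alt_codon)
    counts_as_missense = False
    if alt_aa == STOP and ref_aa != STOP:
        effect = EFFECT_NONSENSE
    elif ref_aa == STOP and alt_aa != STOP:
        effect = EFFECT_STOP_LOSS
    elif (
        at_start_codon
        and ref_codon in code.start_codons
        and alt_codon not in code.start_codons
    ):
        # Initiation is codon-specific, so even a synonymous change away from
        # the initiator is a start-loss; most (e.g. Met1Lys) also change the
        # residue and remain countable as missense.
        effect = EFFECT_START_LOSS
        counts_as_missense = alt_aa != ref_aa
    elif ref_aa == alt_aa:
        effect = EFFECT_SYNONYMOUS
    else:
        effect = EFFECT_MISSENSE
        counts_as_missense = True
    return ref_aa, alt_aa, effect, counts_as_missense


def apply_substitution(
    cds: CodingSequence,
    sub: PointSubstitution,
    code: GeneticCode | None = None,
) -> SubstitutionEffect:
    """Effect of applying one substitution to a codon of ``cds``."""
    code = code or standard_code()
    sub.check_against(cds)
    ref_codon = cds.codon(sub.codon_index)
    alt_codon = (
        ref_codon[: sub.offset - 1] + sub.alt_base + ref_codon[sub.offset :]
    )
    ref_aa, alt_aa, effect, countable = classify_effect(
        ref_codon, alt_codon, code, at_start_codon=(sub.codon_index == 1)
    )
    return SubstitutionEffect(
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=effect,
        mutation_type=classify_substitution(sub.ref_base, sub.alt_base),
        stop_name=STOP_NAMES.get(alt_codon, "none") if alt_aa == STOP else "none",
        counts_as_missense=countable,
    )


def all_substitutions(cds: CodingSequence, include_stop: bool = False) -> Iterator[PointSubstitution]:
    """Every single-nucleotide substitution over the (sense) codons of ``cds``."""
    for i, codon in cds.codons(include_stop=include_stop):
        for off in (1, 2, 3):
            ref = codon[off - 1]
            for alt in NUCLEOTIDES:
                if alt != ref:
                    yield PointSubstitution(i, off, ref, alt)


def stop_adjacent_sense_codons(code: GeneticCode | None = None) -> frozenset[str]:
    """Sense codons with at least one stop codon in their 1-neighborhood."""
    code = code or standard_code()
    stops = code.stop_codons
    return frozenset(
        c for c in code.sense_codons if codon_neighbors(c) & stops
    )
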