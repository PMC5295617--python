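"""File I/O, configuration, packaged reference data, and seeded generators.

Everything the rest of the package needs to be testable without network
access: FASTA and GenBank readers, the packaged lambda Rz coding sequence
and the transcribed mutant-allele table, and deterministic synthetic
generators for coding sequences, embedded-ORF pairs, and covarying aligned
homolog families.

All generators are pure functions of their arguments (including the seed):
the same call always returns byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .covary import GAP, AlignedPairFamily, Homolog
from .mutmap import MutationRecord, parse_mutation_table
from .overlap import OverlapArchitecture, locate_embedded_orf
from .seqcore import (
    NUCLEOTIDES,
    CodingSequence,
    GeneticCode,
    standard_code,
    translate,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ToolConfig:
    """Run configuration recorded in every output header."""

    genetic_code: str = "standard"
    exclude_current: bool = True
    coordinates: str = "1-based-inclusive"
    seed: int = 0
    output_format: str = "tsv"

    def __post_init__(self) -> None:
        if self.coordinates != "1-based-inclusive":
            raise ValueError("coordinate convention is fixed to 1-based-inclusive")
        if self.output_format not in ("tsv", "text"):
            raise ValueError(f"bad output format {self.output_format!r}")

    def header(self) -> str:
        return (
            f"onesnpaway v{__version__} code={self.genetic_code} "
            f"exclude_current={self.exclude_current} coordinates={self.coordinates} "
            f"seed={self.seed} format={self.output_format}"
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ToolConfig":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# FASTA / GenBank
# ---------------------------------------------------------------------------

def read_cds_fasta(path, code: GeneticCode | None = None) -> list[CodingSequence]:
    """Read and validate every record of a FASTA file as a CDS.

    A record whose last codon is a stop is stored with
    ``includes_terminal_stop=True``. Validation failures are reported per
    record, all at once.
    """
    code = code or standard_code()
    out: list[CodingSequence] = []
    errors: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        nt = str(rec.seq).upper()
        try:
            has_stop = len(nt) >= 3 and len(nt) % 3 == 0 and code.is_stop(nt[-3:])
            cds = CodingSequence(id=rec.id, nt=nt, includes_terminal_stop=has_stop)
            cds.validate(code)
            out.append(cds)
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("invalid CDS record(s):\n" + "\n".join(errors))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_cds_fasta(sequences: Iterable[CodingSequence], path) -> None:
    records = [
        SeqRecord(Seq(c.nt), id=c.id, description="") for c in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_gene_from_genbank(
    path, gene_name: str, code: GeneticCode | None = None
) -> CodingSequence:
    """Extract a spliced, strand-corrected CDS by gene name from a GenBank file.

    Matches the ``gene`` or ``locus_tag`` qualifiers (case-insensitive).
    When the feature carries a ``/translation``, the extracted CDS must
    translate to it. A missing gene raises an error listing available names.
    """
    code = code or standard_code()
    available: list[str] = []
    for record in SeqIO.parse(str(path), "genbank"):
        for feat in record.features:
            if feat.type != "CDS":
                continue
            names = feat.qualifiers.get("gene", []) + feat.qualifiers.get("locus_tag", [])
            available.extend(names)
            if any(n.lower() == gene_name.lower() for n in names):
                nt = str(feat.extract(record.seq)).upper()
                has_stop = len(nt) % 3 == 0 and code.is_stop(nt[-3:])
                cds = CodingSequence(id=gene_name, nt=nt, includes_terminal_stop=has_stop)
                cds.validate(code)
                annotated = feat.qualifiers.get("translation", [None])[0]
                if annotated is not None and translate(cds, code) != annotated:
                    raise ValueError(
                        f"{gene_name}: extracted CDS does not translate to the "
                        "annotated protein"
                    )
                return cds
    raise ValueError(
        f"gene {gene_name!r} not found; available CDS genes: "
        + (", ".join(sorted(set(available))) or "(none)")
    )


# ---------------------------------------------------------------------------
# Packaged reference data (phage lambda spanin genes, mutant-allele table)
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("onesnpaway").joinpath("data", name)))


def lambda_rz_cds() -> CodingSequence:
    """The packaged lambda Rz CDS (462 nt: 153 sense codons + stop).

    Transcribed from the public accession NC_001416.1, positions
    45966..46427.
    """
    return read_cds_fasta(_data_path("lambda_rz_cds.fasta"))[0]


def lambda_architecture() -> OverlapArchitecture:
    """Lambda Rz with the embedded Rz1 ORF located in its +1 frame."""
    rz = lambda_rz_cds()
    candidates = locate_embedded_orf(rz, frame_shift=1)
    arch = candidates[0]
    return OverlapArchitecture(
        parent=arch.parent,
        embed_nt_offset=arch.embed_nt_offset,
        embed_codon_count=arch.embed_codon_count,
        embed_id="Rz1",
    )


def lambda_rz1_cds() -> CodingSequence:
    """The lambda Rz1 CDS (60 sense codons + stop), recovered from Rz's +1 frame."""
    return lambda_architecture().embedded_cds()


def table3_records(gene: str | None = None) -> list[MutationRecord]:
    """The packaged transcription of the published lambda spanin mutant table."""
    records = parse_mutation_table(_data_path("table3_mutants.tsv"))
    if gene is not None:
        records = [r for r in records if r.gene == gene]
    return records


# ---------------------------------------------------------------------------
# Seeded synthetic generators
# ---------------------------------------------------------------------------

def _base_weights(gc_fraction: float) -> np.ndarray:
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError(f"gc_fraction {gc_fraction} must be in (0, 1)")
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return np.array([at, gc, gc, at])  # order A, C, G, T


def _sample_codon(rng: np.random.Generator, weights: np.ndarray) -> str:
    idx = rng.choice(4, size=3, p=weights)
    return "".join(NUCLEOTIDES[i] for i in idx)


def generate_cds(
    seed: int, n_codons: int, gc_fraction: float = 0.5, id: str | None = None
) -> CodingSequence:
    """A random valid CDS: ATG start, ``n_codons`` sense codons, one terminal stop.

    ``gc_fraction`` biases base sampling of the internal codons. Deterministic
    per (seed, n_codons, gc_fraction).
    """
    if n_codons < 1:
        raise ValueError("need at least 1 sense codon")
    rng = np.random.default_rng(seed)
    weights = _base_weights(gc_fraction)
    code = standard_code()
    codons = ["ATG"]
    while len(codons) < n_codons:
        codon = _sample_codon(rng, weights)
        if not code.is_stop(codon):
            codons.append(codon)
    stops = sorted(code.stop_codons)
    codons.append(stops[rng.integers(len(stops))])
    return CodingSequence(
        id=id or f"synth-cds-seed{seed}", nt="".join(codons), includes_terminal_stop=True
    )


def generate_embedded_pair(
    seed: int,
    parent_codons: int = 153,
    embed_offset: int = 220,
    embed_codons: int = 60,
    gc_fraction: float = 0.5,
    max_attempts: int = 50,
) -> OverlapArchitecture:
    """A random parent CDS with an embedded ORF planted in a shifted frame.

    Defaults mirror the lambda spanin geometry: a 153-sense-codon parent with
    a 60-sense-codon ORF at nucleotide offset 220 (+1 frame). The parent is
    built by per-codon rejection sampling with backtracking so that both
    frames satisfy their start/stop/no-internal-stop invariants, then checked
    so the planted ORF is the top candidate of :func:`locate_embedded_orf`
    (re-sampling otherwise). Deterministic per arguments. Raises if the
    geometry cannot be satisfied within ``max_attempts``.
    """
    if embed_offset % 3 not in (1, 2):
        raise ValueError("embed_offset must put the ORF in the +1 or +2 frame")
    span = 3 * (embed_codons + 1)
    if embed_offset < 0 or embed_offset + span > 3 * parent_codons:
        raise ValueError(
            f"embedded span ({span} nt at offset {embed_offset}) exceeds the "
            f"parent's sense region ({3 * parent_codons} nt)"
        )
    code = standard_code()
    last_err = "unsatisfiable"
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        nt = _build_embedded_parent(
            rng, parent_codons, embed_offset, embed_codons, gc_fraction, code
        )
        if nt is None:
            last_err = "backtracking exhausted"
            continue
        parent = CodingSequence(
            id=f"synth-pair-seed{seed}", nt=nt, includes_terminal_stop=True
        )
        shift = embed_offset % 3
        candidates = locate_embedded_orf(parent, frame_shift=shift)
        if (
            candidates
            and candidates[0].embed_nt_offset == embed_offset
            and candidates[0].embed_codon_count == embed_codons + 1
        ):
            return OverlapArchitecture(
                parent=parent,
                embed_nt_offset=embed_offset,
                embed_codon_count=embed_codons + 1,
                embed_id=f"synth-embedded-seed{seed}",
            )
        last_err = "planted ORF is not the top located candidate"
    raise RuntimeError(
        f"could not generate an embedded pair after {max_attempts} attempts "
        f"({last_err}); try a different seed or geometry"
    )


def _build_embedded_parent(
    rng: np.random.Generator,
    parent_codons: int,
    embed_offset: int,
    embed_codons: int,
    gc_fraction: float,
    code: GeneticCode,
) -> str | None:
    """Depth-first per-codon construction honoring both frames; None on failure."""
    weights = _base_weights(gc_fraction)
    total_codons = parent_codons + 1
    n_nt = 3 * total_codons
    span_end = embed_offset + 3 * (embed_codons + 1)

    # Pinned bases: embedded ATG and a pre-chosen embedded stop codon.
    stops = sorted(code.stop_codons)
    emb_stop = stops[rng.integers(len(stops))]
    pinned: dict[int, str] = {embed_offset + k: "ATG"[k] for k in range(3)}
    pinned.update({span_end - 3 + k: emb_stop[k] for k in range(3)})

    def emb_codon_bounds(j: int) -> tuple[int, int]:
        start = embed_offset + 3 * j
        return start, start + 3

    n_emb = embed_codons + 1

    def candidates_for(i: int) -> list[str]:
        """Parent codon i (0-based) candidates in randomized weighted order."""
        if i == 0:
            pool = ["ATG"]
        elif i == total_codons - 1:
            pool = list(stops)
            rng.shuffle(pool)
        else:
            pool = [c for c in sorted(code.sense_codons)]
            w = np.array(
                [np.prod([weights[NUCLEOTIDES.index(b)] for b in c]) for c in pool]
            )
            keys = np.log(w) + rng.gumbel(size=len(pool))
            pool = [pool[k] for k in np.argsort(-keys)]
        out = []
        for codon in pool:
            ok = True
            for k in range(3):
                p = 3 * i + k
                if p in pinned and pinned[p] != codon[k]:
                    ok = False
                    break
            if ok:
                out.append(codon)
        return out

    nt = [""] * n_nt
    steps = 0
    max_steps = 200 * total_codons

    def place(i: int) -> bool:
        nonlocal steps
        steps += 1
        if steps > max_steps:
            return False
        if i == total_codons:
            return True
        for codon in candidates_for(i):
            for k in range(3):
                nt[3 * i + k] = codon[k]
            # any embedded middle codon completed by this placement must be non-stop
            ok = True
            for j in range(n_emb):
                lo, hi = emb_codon_bounds(j)
                if hi <= 3 * (i + 1) and hi > 3 * i:  # completed within/at this codon
                    emb = "".join(nt[lo:hi])
                    if 0 < j < n_emb - 1 and code.is_stop(emb):
                        ok = False
                        break
            if ok and place(i + 1):
                return True
        for k in range(3):
            nt[3 * i + k] = ""
        return False

    if not place(0):
        return None
    return "".join(nt)


def generate_family(
    seed: int,
    n_homologs: int = 6,
    len_a: int = 20,
    len_b: int = 18,
    planted_pairs: Sequence[tuple[int, int]] = ((17, 16),),
    conservation: float = 0.7,
    charge_noise: float = 0.0,
) -> AlignedPairFamily:
    """A synthetic aligned homolog family with planted charge-covarying pairs.

    Defaults emulate the published analysis geometry: six homologs, a
    20-column i-spanin C-terminal segment and an 18-column o-spanin
    C-terminal segment, with one planted complementary pair near both
    C-termini. Planted columns carry strictly complementary charges
    (one partner positive where the other is negative) with at least one
    sign swap across homologs. Background columns are drawn independently
    around per-column consensus residues, with variation confined to the
    consensus residue's charge class (chemically conservative drift, the
    dominant mode in real homolog alignments); ``charge_noise`` is the
    per-residue probability of breaking that confinement. Deterministic per
    arguments.
    """
    if n_homologs < 2:
        raise ValueError("need >= 2 homologs")
    cols_a = set()
    cols_b = set()
    for a, b in planted_pairs:
        if not (1 <= a <= len_a and 1 <= b <= len_b):
            raise ValueError(f"planted pair ({a}, {b}) outside segment lengths")
        if a in cols_a or b in cols_b:
            raise ValueError("planted columns overlap")
        cols_a.add(a)
        cols_b.add(b)
    rng = np.random.default_rng(seed)

    from .covary import CHARGE_CLASSES

    class_members: dict[str, str] = {}
    for aa in AA20:
        class_members.setdefault(CHARGE_CLASSES[aa], "")
    for aa in AA20:
        class_members[CHARGE_CLASSES[aa]] += aa

    def background_column() -> list[str]:
        consensus = AA20[rng.integers(len(AA20))]
        same_class = class_members[CHARGE_CLASSES[consensus]]
        col = []
        for _ in range(n_homologs):
            if rng.random() < charge_noise:
                col.append(AA20[rng.integers(len(AA20))])
            elif rng.random() < conservation:
                col.append(consensus)
            else:
                col.append(same_class[rng.integers(len(same_class))])
        return col

    mat_a = {c: background_column() for c in range(1, len_a + 1) if c not in cols_a}
    mat_b = {c: background_column() for c in range(1, len_b + 1) if c not in cols_b}
    positive, negative = "KR", "DE"
    for a, b in planted_pairs:
        signs = rng.integers(0, 2, size=n_homologs)
        if len(set(signs.tolist())) < 2:  # force >=1 sign swap
            signs[rng.integers(n_homologs)] ^= 1
        col_a, col_b = [], []
        for s in signs:
            if s:
                col_a.append(positive[rng.integers(2)])
                col_b.append(negative[rng.integers(2)])
            else:
                col_a.append(negative[rng.integers(2)])
                col_b.append(positive[rng.integers(2)])
        mat_a[a] = col_a
        mat_b[b] = col_b
    homologs = tuple(
        Homolog(
            label=f"homolog{h + 1}",
            segment_a="".join(mat_a[c][h] for c in range(1, len_a + 1)),
            segment_b="".join(mat_b[c][h] for c in range(1, len_b + 1)),
        )
        for h in range(n_homologs)
    )
    return AlignedPairFamily(homologs)


def read_family_fasta(path_a, path_b) -> AlignedPairFamily:
    """Build a family from two aligned FASTA files with matching record order."""
    recs_a = list(SeqIO.parse(str(path_a), "fasta"))
    recs_b = list(SeqIO.parse(str(path_b), "fasta"))
    if len(recs_a) != len(recs_b):
        raise ValueError(
            f"partner alignments differ in record count ({len(recs_a)} vs {len(recs_b)})"
        )
    return AlignedPairFamily(
        tuple(
            Homolog(label=a.id, segment_a=str(a.seq).upper(), segment_b=str(b.seq).upper())
            for a, b in zip(recs_a, recs_b)
        )
    )


def write_family_fasta(family: AlignedPairFamily, path_a, path_b) -> None:
    SeqIO.write(
        [SeqRecord(Seq(h.segment_a), id=h.label, description="") for h in family.homologs],
        str(path_a),
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(h.segment_b), id=h.label, description="") for h in family.homologs],
        str(path_b),
        "fasta",
    )
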