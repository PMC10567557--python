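"""Canonical data model for pegRNA designs and basic sequence utilities.

Orientation convention
----------------------
Inserts are stored as *written* sequences: 5'→3' on the edited (nicked)
genomic strand, i.e. the reverse complement of the pegRNA-side template.
All pegRNA-side sequences are derived, never stored, so there is a single
source of truth for orientation.

The nick is a zero-width boundary between the upstream and downstream
flanks; offsets such as the "+9" variant position are 1-based counting
downstream of the nick.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

#: 86-nt improved sgRNA scaffold used for pegRNA expression cassettes.
IMPROVED_SCAFFOLD = (
    "GTTTAAGAGCTATGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTCCGTTATCAACT"
    "TGAAAAAGTGGCACCGAGTCGGTGC"
)

#: Default pegRNA geometry: 13-nt primer binding site, 34-nt homology arm.
DEFAULT_PBS_LEN = 13
DEFAULT_HA_LEN = 34


class InvalidSequenceError(ValueError):
    """Raised for sequences outside the {A,C,G,T} alphabet or empty input."""


def _validate_dna(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise InvalidSequenceError(f"{name} must be non-empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"{name} contains non-ACGT characters: {sorted(bad)}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of a DNA string.

    Raises :class:`InvalidSequenceError` on empty input or characters
    outside {A,C,G,T}.
    """
    _validate_dna(seq)
    return str(Seq(seq).reverse_complement())


def dna_to_rna(seq: str) -> str:
    """Transcribe a DNA string to RNA (T→U), preserving orientation."""
    return seq.replace("T", "U")


def max_homopolymer_run(seq: str, base: str) -> int:
    """Length of the longest run of ``base`` in ``seq`` (0 if absent)."""
    _validate_dna(seq)
    if base not in DNA_ALPHABET:
        raise InvalidSequenceError(f"base must be one of ACGT, got {base!r}")
    return max(
        (len(list(g)) for b, g in itertools.groupby(seq) if b == base),
        default=0,
    )


@dataclass(frozen=True)
class InsertSequence:
    """A candidate insertion, written-strand orientation.

    Parameters
    ----------
    id : str
        Unique identifier within a library.
    written_seq : str
        The insert 5'→3' as it appears on the edited genomic strand
        (reverse complement of the pegRNA-side template). 1–200 nt.
    category : str, optional
        Free-form label (utility tag, linear motif, structure set, random).
    """

    id: str
    written_seq: str
    category: Optional[str] = None

    def __post_init__(self) -> None:
        _validate_dna(self.written_seq, f"insert {self.id!r}")
        if not 1 <= len(self.written_seq) <= 200:
            raise InvalidSequenceError(
                f"insert {self.id!r} length {len(self.written_seq)} outside [1, 200]"
            )

    def __len__(self) -> int:
        return len(self.written_seq)


@dataclass(frozen=True)
class KnownVariant:
    """A known non-reference allele near the nick (e.g. the +9 A allele).

    ``position`` is 1-based downstream of the nick on the edited strand.
    """

    position: int
    ref: str
    alt: str
    alt_frequency: float = 0.0


@dataclass(frozen=True)
class TargetSite:
    """A genomic target locus, described relative to the nick boundary.

    ``flank_up`` is immediately 5' of the nick on the edited strand,
    ``flank_down`` immediately 3'. Flank lengths must cover the matching
    windows they serve: ≥10 up / ≥60 down for the target amplicon and
    ≥15/15 for the pegRNA amplicon anchors.
    """

    name: str
    flank_up: str
    flank_down: str
    known_variant: Optional[KnownVariant] = None

    def __post_init__(self) -> None:
        _validate_dna(self.flank_up, "flank_up")
        _validate_dna(self.flank_down, "flank_down")
        if len(self.flank_up) < 10:
            raise InvalidSequenceError("flank_up must be >= 10 nt")
        if len(self.flank_down) < 60:
            raise InvalidSequenceError("flank_down must be >= 60 nt")

    @property
    def nick_site_base(self) -> str:
        """The single genomic base immediately 3' of the nick (+1 position)."""
        return self.flank_down[0]


@dataclass(frozen=True)
class ScreenContext:
    """Cellular / experimental context of one screen replicate.

    ``mean_log_efficiency`` / ``sd_log_efficiency`` carry the screen's
    location and scale so that model z-scores can be inverted back to
    percent editing rates.
    """

    screen_id: str
    cell_line: str
    mmr_proficient: bool
    editor: str = "PE2"
    replicate: str = "r1"
    mean_log_efficiency: Optional[float] = None
    sd_log_efficiency: Optional[float] = None

    _EDITORS = ("PE2", "PE3", "PE-FeLV", "epegRNA")

    def __post_init__(self) -> None:
        if self.editor not in self._EDITORS:
            raise ValueError(f"editor must be one of {self._EDITORS}")
        if self.sd_log_efficiency is not None and self.sd_log_efficiency <= 0:
            raise ValueError("sd_log_efficiency must be > 0 when set")


@dataclass(frozen=True)
class PegRNADesign:
    """The five-part pegRNA plus its target-site context.

    All parts are DNA strings; ``homology_arm`` is in written-strand
    orientation (it matches the genome immediately downstream of the nick).
    """

    spacer: str
    insert: InsertSequence
    homology_arm: str
    pbs: str
    target_site: TargetSite
    scaffold: str = IMPROVED_SCAFFOLD

    def __post_init__(self) -> None:
        _validate_dna(self.spacer, "spacer")
        _validate_dna(self.homology_arm, "homology_arm")
        _validate_dna(self.pbs, "pbs")
        _validate_dna(self.scaffold, "scaffold")

    @property
    def rtt(self) -> str:
        """Reverse-transcriptase template (DNA, pegRNA orientation).

        The RT primes at the nick and copies the insert first, so the
        template reads revcomp(insert + HA): revcomp(HA) at its 5' end
        (scaffold-adjacent) and revcomp(insert) at its 3' end, immediately
        5' of the PBS.
        """
        return reverse_complement(self.insert.written_seq + self.homology_arm)

    @property
    def extension_dna(self) -> str:
        """The 3' extension (RTT + PBS) as DNA, 5'→3'."""
        return self.rtt + self.pbs

    @property
    def full_sequence_rna(self) -> str:
        """Full pegRNA molecule: spacer + scaffold + RTT + PBS, as RNA."""
        return dna_to_rna(self.spacer + self.scaffold + self.extension_dna)


def assemble_extension(design: PegRNADesign) -> str:
    """pegRNA 3' extension 5'→3' as RNA: RTT followed by PBS.

    RTT = reverse complement of (insert + homology arm); length equals
    \\|HA| + |insert| + |PBS|.
    """
    return dna_to_rna(design.extension_dna)


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

def read_library_fasta(path: str | Path) -> list[InsertSequence]:
    """Read an insert library from FASTA (record id = insert id)."""
    inserts = [
        InsertSequence(id=rec.id, written_seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids(inserts)
    return inserts


def write_library_fasta(inserts: Iterable[InsertSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(i.written_seq), id=i.id, description=i.category or "")
        for i in inserts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_library_tsv(path: str | Path) -> list[InsertSequence]:
    """Read an insert library from a TSV with columns id, written_seq[, category]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    inserts = [
        InsertSequence(
            id=row["id"],
            written_seq=row["written_seq"].upper(),
            category=row.get("category"),
        )
        for _, row in df.iterrows()
    ]
    _check_unique_ids(inserts)
    return inserts


def write_library_tsv(inserts: Iterable[InsertSequence], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"id": i.id, "written_seq": i.written_seq, "category": i.category or ""}
            for i in inserts
        ]
    ).to_csv(path, sep="\t", index=False)


def _check_unique_ids(inserts: list[InsertSequence]) -> None:
    ids = [i.id for i in inserts]
    if len(set(ids)) != len(ids):
        dupes = {x for x in ids if ids.count(x) > 1}
        raise ValueError(f"duplicate insert ids in library: {sorted(dupes)}")


def make_design(
    insert: InsertSequence,
    site: TargetSite,
    spacer: Optional[str] = None,
    pbs_len: int = DEFAULT_PBS_LEN,
    ha_len: int = DEFAULT_HA_LEN,
    scaffold: str = IMPROVED_SCAFFOLD,
) -> PegRNADesign:
    """Build a pegRNA for ``insert`` at ``site`` with default geometry.

    The PBS is the reverse complement of the ``pbs_len`` nt immediately
    upstream of the nick; the homology arm is the first ``ha_len`` nt
    downstream. The spacer, if not given, defaults to the 20 nt ending at
    3 nt downstream of the nick (standard SpCas9 nick placement between
    protospacer positions 17 and 18).
    """
    if len(site.flank_up) < pbs_len:
        raise InvalidSequenceError("flank_up shorter than requested PBS")
    if len(site.flank_down) < ha_len:
        raise InvalidSequenceError("flank_down shorter than requested HA")
    pbs = reverse_complement(site.flank_up[-pbs_len:])
    ha = site.flank_down[:ha_len]
    if spacer is None:
        if len(site.flank_up) < 17:
            raise InvalidSequenceError("flank_up too short to derive a spacer")
        spacer = site.flank_up[-17:] + site.flank_down[:3]
    return PegRNADesign(
        spacer=spacer,
        insert=insert,
        homology_arm=ha,
        pbs=pbs,
        target_site=site,
        scaffold=scaffold,
    )
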