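"""RNA minimum-free-energy folding and background-normalized structure scores.

Folding is delegated to the ViennaRNA nearest-neighbour MFE engine at 37 °C
with the default RNA parameter set; MFE values therefore drift slightly
between parameter-set releases, which is why downstream comparisons carry a
±0.5 kcal/mol slack.

Raw MFE scales with sequence length, so the model feature is a z-score: the
observed MFE standardized against uniform-random inserts of identical length
folded in the identical fixed context (1,000 by default). Negative z means
stronger-than-average structure. Backgrounds are cached per
(length, context, seed) so repeated scoring of a library is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import RNA

from peginsert.core import (
    InvalidSequenceError,
    PegRNADesign,
    dna_to_rna,
    reverse_complement,
)

RNA_ALPHABET = frozenset("ACGU")

FOLD_TEMPERATURE_C = 37.0

#: Stem-loop intervals on the 86-nt improved scaffold, 1-based inclusive:
#: the three hairpins of the scaffold's MFE structure (the repeat:anti-repeat
#: duplex first, then the two 3' hairpins). Boundaries are configuration,
#: not a measured quantity.
DEFAULT_LOOP_COORDS = {
    "loop1": (1, 40),
    "loop2": (59, 70),
    "loop3": (71, 86),
}

#: Minimum number of stem-loop bases that must pair with the insert before
#: the loop is called disrupted; single-base contacts are folding noise.
MIN_DISRUPTION_BASES = 3


class StructureContext(str, Enum):
    """Which pegRNA parts are concatenated (pegRNA strand) before folding."""

    INSERT_ONLY = "insert_only"
    RTT = "rtt"  # insert + homology arm, i.e. the reverse-transcribed template
    PBS_INSERT_HA = "pbs_insert_ha"  # the full 3' extension
    INSERT_SCAFFOLD = "insert_scaffold"


@dataclass(frozen=True)
class FoldResult:
    """MFE and one MFE structure for a single RNA sequence."""

    mfe_kcal_mol: float
    structure: str  # dot-bracket
    pair_table: tuple  # 0-based partner index per position, -1 if unpaired

    def paired_with(self, i: int) -> int:
        return self.pair_table[i]


@dataclass(frozen=True)
class StructureZScore:
    value: float
    context: StructureContext
    mfe_kcal_mol: float
    background_mean: float
    background_sd: float
    n_background: int
    seed: int
    degenerate: bool = False  # background sd was 0; value forced to 0


def fold_mfe(rna: str) -> FoldResult:
    """Fold a single RNA strand and return its MFE structure.

    Deterministic; 37 °C, standard RNA nearest-neighbour parameters.
    A sequence with no possible pairs returns 0.0 kcal/mol, all unpaired.
    """
    if not rna:
        raise InvalidSequenceError("cannot fold an empty sequence")
    bad = set(rna) - RNA_ALPHABET
    if bad:
        raise InvalidSequenceError(f"non-ACGU characters in RNA: {sorted(bad)}")
    structure, mfe = RNA.fold(rna)
    return FoldResult(
        mfe_kcal_mol=round(float(mfe), 2),
        structure=structure,
        pair_table=_pair_table(structure),
    )


def _pair_table(structure: str) -> tuple:
    """0-based partner indices from a dot-bracket string (-1 = unpaired)."""
    pt = RNA.ptable(structure)
    return tuple(p - 1 if p > 0 else -1 for p in pt[1:])


def context_rna(design: PegRNADesign, context: StructureContext) -> str:
    """The pegRNA-strand RNA folded for a given structure context.

    On the molecule the regions read 5'→3': scaffold, revcomp(HA),
    revcomp(insert), PBS. The insert-only and insert+scaffold contexts use
    the pegRNA-side insert in isolation, as the field convention does.
    """
    ins_peg = reverse_complement(design.insert.written_seq)
    if context is StructureContext.INSERT_ONLY:
        dna = ins_peg
    elif context is StructureContext.RTT:
        dna = design.rtt
    elif context is StructureContext.PBS_INSERT_HA:
        dna = design.extension_dna
    elif context is StructureContext.INSERT_SCAFFOLD:
        dna = design.scaffold + ins_peg
    else:  # pragma: no cover
        raise ValueError(f"unknown context {context}")
    return dna_to_rna(dna)


def _context_template(design: PegRNADesign, context: StructureContext):
    """(prefix, suffix) DNA around the written-insert slot for a context.

    Background sequences are random inserts dropped into this fixed frame,
    so prefix/suffix must be expressed in terms of the *written* insert.
    The pegRNA-strand RNA for written insert ``x`` is
    prefix + revcomp(x) + suffix.
    """
    if context is StructureContext.INSERT_ONLY:
        return "", ""
    if context is StructureContext.RTT:
        # RTT = revcomp(insert + HA) = revcomp(HA) + revcomp(insert)
        return reverse_complement(design.homology_arm), ""
    if context is StructureContext.PBS_INSERT_HA:
        return reverse_complement(design.homology_arm), design.pbs
    if context is StructureContext.INSERT_SCAFFOLD:
        return design.scaffold, ""
    raise ValueError(f"unknown context {context}")


# Cache of background (mean, sd) keyed by
# (insert length, prefix, suffix, n_background, seed).
_BACKGROUND_CACHE: dict = {}


def clear_background_cache() -> None:
    _BACKGROUND_CACHE.clear()


def _background_stats(
    length: int, prefix: str, suffix: str, n_background: int, seed: int
) -> tuple[float, float]:
    key = (length, prefix, suffix, n_background, seed)
    cached = _BACKGROUND_CACHE.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    mfes = np.empty(n_background)
    for i in range(n_background):
        ins = "".join(rng.choice(bases, size=length))
        rna = dna_to_rna(prefix + reverse_complement(ins) + suffix)
        _, mfe = RNA.fold(rna)
        mfes[i] = mfe
    stats = (float(mfes.mean()), float(mfes.std()))
    _BACKGROUND_CACHE[key] = stats
    return stats


def structure_zscore(
    design: PegRNADesign,
    context: StructureContext = StructureContext.RTT,
    n_background: int = 1000,
    seed: int = 0,
) -> StructureZScore:
    """MFE of the design in ``context``, standardized against random inserts.

    z = (MFE_observed − mean_bg) / sd_bg over ``n_background`` uniform-random
    inserts of identical length placed in the identical fixed context.
    Negative z = stronger-than-average structure. A degenerate background
    (sd 0, e.g. 1-nt inserts in no context) reports z = 0 with a flag.
    """
    if n_background < 100:
        raise ValueError("n_background must be >= 100")
    observed = fold_mfe(context_rna(design, context))
    prefix, suffix = _context_template(design, context)
    mean_bg, sd_bg = _background_stats(
        len(design.insert), prefix, suffix, n_background, seed
    )
    if sd_bg == 0.0:
        return StructureZScore(
            value=0.0,
            context=context,
            mfe_kcal_mol=observed.mfe_kcal_mol,
            background_mean=mean_bg,
            background_sd=0.0,
            n_background=n_background,
            seed=seed,
            degenerate=True,
        )
    z = (observed.mfe_kcal_mol - mean_bg) / sd_bg
    return StructureZScore(
        value=float(z),
        context=context,
        mfe_kcal_mol=observed.mfe_kcal_mol,
        background_mean=mean_bg,
        background_sd=sd_bg,
        n_background=n_background,
        seed=seed,
    )


def spacer_pairing_count(design: PegRNADesign) -> int:
    """Paired bases between the insert's first 3 nt and the spacer 3' end.

    The PBS is complementary to most of the protospacer and hybridizes with
    it within the pegRNA; if the insert-proximal nucleotides extend this
    duplex into the last 3 nt of the spacer (plus the first scaffold G), the
    protospacer can be sequestered. Counted on a two-strand MFE co-fold of
    (spacer + first scaffold nt) with (revcomp(first 3 written insert nt) +
    PBS), which avoids artifactual linker pairings.

    Returns the number of the (up to 3) insert-side nucleotides paired with
    the spacer/first-scaffold-G strand, capped at the insert length.
    """
    k = min(3, len(design.insert))
    strand_a = dna_to_rna(design.spacer + design.scaffold[0])
    ins_side = reverse_complement(design.insert.written_seq[:k])
    strand_b = dna_to_rna(ins_side + design.pbs)
    structure, _ = RNA.cofold(strand_a + "&" + strand_b)
    pt = _pair_table(structure.replace("&", ""))
    la = len(strand_a)
    count = 0
    for i in range(la, la + k):  # the k insert-side positions on strand B
        partner = pt[i]
        if 0 <= partner < la:
            count += 1
    return count


def loop_disruption(
    design: PegRNADesign,
    loop_coords: Optional[dict] = None,
) -> str:
    """Does the insert pair into a scaffold stem-loop in the MFE fold?

    Folds the full scaffold concatenated with the pegRNA-strand insert and
    reports ``"loop1"`` if at least :data:`MIN_DISRUPTION_BASES` bases of
    stem-loop 1 pair with insert bases, ``"loop2or3"`` analogously (loop1
    takes precedence), else ``"none"``.
    """
    coords = dict(DEFAULT_LOOP_COORDS if loop_coords is None else loop_coords)
    scaffold_len = len(design.scaffold)
    for name, (lo, hi) in coords.items():
        if hi > scaffold_len:
            raise ValueError(
                f"{name} interval ({lo}, {hi}) exceeds scaffold length {scaffold_len}"
            )
    rna = dna_to_rna(design.scaffold + reverse_complement(design.insert.written_seq))
    pt = _pair_table(RNA.fold(rna)[0])

    def region_hits_insert(lo: int, hi: int) -> bool:
        n_hits = sum(1 for i in range(lo - 1, hi) if pt[i] >= scaffold_len)
        return n_hits >= MIN_DISRUPTION_BASES

    if region_hits_insert(*coords["loop1"]):
        return "loop1"
    if region_hits_insert(*coords["loop2"]) or region_hits_insert(*coords["loop3"]):
        return "loop2or3"
    return "none"
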