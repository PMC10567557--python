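"""Model feature assembly for pegRNA designs.

The core model uses ten features of the written insert and its context:
length; %C, %A, %T (%G is implicit to avoid collinearity); the structure
z-score of the reverse-transcribed template (insert + homology arm); MMR
proficiency of the cell line; the number of insert nucleotides pairing into
the spacer 3' end; complementarity of the first insert nucleotide with the
nick-site base; the maximum adenine run (a run of >=4 A makes a Pol-III
terminator on the U6 cassette); and intactness of scaffold loop 1.

An extended 53-feature set adds melting temperature, alternative folding
contexts, dinucleotide fractions and further cheap sequence descriptors.
The exact roster of the extended set beyond the named features is a
package choice, versioned by ``EXTENDED_MANIFEST``.

All composition features are computed on the written (genomic-strand)
insert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp

from peginsert.core import (
    PegRNADesign,
    ScreenContext,
    max_homopolymer_run,
    reverse_complement,
)
from peginsert.structure import StructureContext, fold_mfe, context_rna, structure_zscore

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Stable column order of the 10-feature model matrix.
CORE_MANIFEST = [
    "length",
    "pct_C",
    "pct_A",
    "pct_T",
    "rtt_structure_z",
    "mmr_proficient",
    "spacer_pairing",
    "first_nt_nick_complement",
    "max_A_run",
    "loop1_intact",
]

_DINUCS = ["".join(p) for p in product("ACGT", repeat=2)]

#: Extended manifest (53 features), version 1.
EXTENDED_MANIFEST = CORE_MANIFEST + [
    "melting_temp_c",
    "insert_structure_z",
    "extension_structure_z",
    "pct_G",
    "pct_GC",
    "pct_purine",
    "loop2or3_disrupted",
    "polyA_terminator",
    "length_bin",
    "max_C_run",
    "max_G_run",
    "max_T_run",
    "max_any_run",
    "rtt_mfe_kcal_mol",
    "extension_length",
    "pbs_length",
    "ha_length",
    "composition_entropy",
    "gc_skew",
    "first_nt_A",
    "first_nt_C",
    "first_nt_G",
    "first_nt_T",
    "last_nt_A",
    "last_nt_C",
    "last_nt_G",
    "last_nt_T",
] + [f"dinuc_{d}" for d in _DINUCS]

assert len(EXTENDED_MANIFEST) == 53

#: Length bins used for length-relative rates; <10 nt uses exact length.
LENGTH_BINS = [(10, 14), (15, 19), (20, 24), (25, 29), (30, 39), (40, 49), (50, 59), (60, 69)]


def length_bin_label(length: int) -> str:
    """Bin id for a given insert length (exact length below 10 nt)."""
    if length < 10:
        return str(length)
    for lo, hi in LENGTH_BINS:
        if lo <= length <= hi:
            return f"{lo}-{hi}"
    return f">{LENGTH_BINS[-1][1]}"


def first_nt_nick_complement(design: PegRNADesign) -> bool:
    """True iff the first written insert nt is the Watson–Crick complement
    of the genomic base at the +1 position after the nick."""
    nick_base = design.target_site.nick_site_base
    if nick_base not in _COMPLEMENT:
        raise ValueError(f"invalid nick-site base {nick_base!r}")
    return _COMPLEMENT[design.insert.written_seq[0]] == nick_base


def melting_temperature(insert_seq: str) -> float:
    """Nearest-neighbour melting temperature of the insert (°C).

    Default nearest-neighbour table and salt conditions of
    ``Bio.SeqUtils.MeltingTemp.Tm_NN`` (SantaLucia 2004, 50 mM Na+).
    """
    return float(MeltingTemp.Tm_NN(insert_seq))


@dataclass(frozen=True)
class FeatureVector:
    """The 10 model features for one design in one screen context."""

    length: int
    pct_C: float
    pct_A: float
    pct_T: float
    rtt_structure_z: float
    mmr_proficient: bool
    spacer_pairing: int
    first_nt_nick_complement: bool
    max_A_run: int
    loop1_intact: bool

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "length": self.length,
                "pct_C": self.pct_C,
                "pct_A": self.pct_A,
                "pct_T": self.pct_T,
                "rtt_structure_z": self.rtt_structure_z,
                "mmr_proficient": float(self.mmr_proficient),
                "spacer_pairing": self.spacer_pairing,
                "first_nt_nick_complement": float(self.first_nt_nick_complement),
                "max_A_run": self.max_A_run,
                "loop1_intact": float(self.loop1_intact),
            }
        )[CORE_MANIFEST]


def _pct(seq: str, base: str) -> float:
    return 100.0 * seq.count(base) / len(seq)


def featurize(
    design: PegRNADesign,
    context: ScreenContext,
    n_background: int = 1000,
    seed: int = 0,
    loop_call: Optional[str] = None,
    rtt_z: Optional[float] = None,
    spacer_pairing: Optional[int] = None,
) -> FeatureVector:
    """Assemble the 10-feature vector for one design in one context.

    Deterministic given ``seed`` (which controls the structure background).
    The structure-derived features may be supplied precomputed to avoid
    refolding when featurizing the same design in several screen contexts.
    """
    from peginsert.structure import loop_disruption, spacer_pairing_count

    seq = design.insert.written_seq
    if rtt_z is None:
        rtt_z = structure_zscore(
            design, StructureContext.RTT, n_background=n_background, seed=seed
        ).value
    if spacer_pairing is None:
        spacer_pairing = spacer_pairing_count(design)
    if loop_call is None:
        loop_call = loop_disruption(design)
    return FeatureVector(
        length=len(seq),
        pct_C=_pct(seq, "C"),
        pct_A=_pct(seq, "A"),
        pct_T=_pct(seq, "T"),
        rtt_structure_z=rtt_z,
        mmr_proficient=context.mmr_proficient,
        spacer_pairing=spacer_pairing,
        first_nt_nick_complement=first_nt_nick_complement(design),
        max_A_run=max_homopolymer_run(seq, "A"),
        loop1_intact=loop_call != "loop1",
    )


def feature_matrix(
    designs: Sequence[PegRNADesign],
    contexts: Sequence[ScreenContext],
    n_background: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """10-feature matrix for paired (design, context) rows.

    ``designs`` and ``contexts`` must be equally long; row ``i`` is design
    ``i`` in context ``i``. Structure features are computed once per unique
    design. Columns follow :data:`CORE_MANIFEST`; the index carries the
    insert ids.
    """
    if len(designs) != len(contexts):
        raise ValueError("designs and contexts must align")
    cache: dict = {}
    rows = []
    for design, ctx in zip(designs, contexts):
        key = (design.insert.written_seq, design.homology_arm, design.spacer, design.pbs)
        if key not in cache:
            from peginsert.structure import loop_disruption, spacer_pairing_count

            cache[key] = (
                structure_zscore(design, StructureContext.RTT, n_background, seed).value,
                spacer_pairing_count(design),
                loop_disruption(design),
            )
        rtt_z, pairing, loop_call = cache[key]
        fv = featurize(
            design, ctx, n_background, seed,
            loop_call=loop_call, rtt_z=rtt_z, spacer_pairing=pairing,
        )
        rows.append(fv.to_series().rename(design.insert.id))
    return pd.DataFrame(rows)


def extended_features(
    design: PegRNADesign,
    context: ScreenContext,
    n_background: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """The 53-feature extended vector (superset of the core ten)."""
    from peginsert.structure import loop_disruption

    core = featurize(design, context, n_background, seed).to_series()
    seq = design.insert.written_seq
    n = len(seq)
    loop_call = loop_disruption(design)
    rtt_fold = fold_mfe(context_rna(design, StructureContext.RTT))
    counts = {b: seq.count(b) for b in "ACGT"}
    entropy = -sum(
        (c / n) * math.log2(c / n) for c in counts.values() if c > 0
    )
    ext = {
        "melting_temp_c": melting_temperature(seq),
        "insert_structure_z": structure_zscore(
            design, StructureContext.INSERT_ONLY, n_background, seed
        ).value,
        "extension_structure_z": structure_zscore(
            design, StructureContext.PBS_INSERT_HA, n_background, seed
        ).value,
        "pct_G": _pct(seq, "G"),
        "pct_GC": _pct(seq, "G") + _pct(seq, "C"),
        "pct_purine": _pct(seq, "A") + _pct(seq, "G"),
        "loop2or3_disrupted": float(loop_call == "loop2or3"),
        "polyA_terminator": float(max_homopolymer_run(seq, "A") >= 4),
        "length_bin": float(_bin_index(n)),
        "max_C_run": max_homopolymer_run(seq, "C"),
        "max_G_run": max_homopolymer_run(seq, "G"),
        "max_T_run": max_homopolymer_run(seq, "T"),
        "max_any_run": max(max_homopolymer_run(seq, b) for b in "ACGT"),
        "rtt_mfe_kcal_mol": rtt_fold.mfe_kcal_mol,
        "extension_length": len(design.extension_dna),
        "pbs_length": len(design.pbs),
        "ha_length": len(design.homology_arm),
        "composition_entropy": entropy,
        "gc_skew": (counts["G"] - counts["C"]) / (counts["G"] + counts["C"])
        if counts["G"] + counts["C"]
        else 0.0,
    }
    for b in "ACGT":
        ext[f"first_nt_{b}"] = float(seq[0] == b)
        ext[f"last_nt_{b}"] = float(seq[-1] == b)
    n_dinucs = max(n - 1, 1)
    for d in _DINUCS:
        ext[f"dinuc_{d}"] = sum(
            1 for i in range(n - 1) if seq[i : i + 2] == d
        ) / n_dinucs
    return pd.concat([core, pd.Series(ext)])[EXTENDED_MANIFEST]


def _bin_index(length: int) -> int:
    if length < 10:
        return length
    for i, (lo, hi) in enumerate(LENGTH_BINS):
        if lo <= length <= hi:
            return 10 + i
    return 10 + len(LENGTH_BINS)


def write_feature_matrix(
    matrix: pd.DataFrame, path, seed: int = 0, manifest_version: str = "core-1"
) -> None:
    """Write a feature matrix as TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# peginsert feature matrix; manifest={manifest_version}; seed={seed}\n")
        matrix.to_csv(fh, sep="\t", index_label="id")
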