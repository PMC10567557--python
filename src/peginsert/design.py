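"""Practical pegRNA design operations.

Codon-variant enumeration (exhaustive, or restricted to the top two human
codons per residue for longer tags), model-based ranking with a poly-A
terminator flag, and padding of short inserts to the favourable 15–21 nt
length range.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import pandas as pd

from peginsert.core import (
    InsertSequence,
    PegRNADesign,
    ScreenContext,
    TargetSite,
    make_design,
    max_homopolymer_run,
)
from peginsert.features import feature_matrix
from peginsert.model import TrainedModel

#: Human codon usage, codons ordered by decreasing usage fraction
#: (standard human codon-usage frequencies; replaceable via config).
HUMAN_CODON_USAGE = {
    "A": [("GCC", 0.40), ("GCT", 0.27), ("GCA", 0.23), ("GCG", 0.11)],
    "R": [("CGG", 0.21), ("AGA", 0.21), ("AGG", 0.21), ("CGC", 0.18), ("CGA", 0.11), ("CGT", 0.08)],
    "N": [("AAC", 0.53), ("AAT", 0.47)],
    "D": [("GAC", 0.54), ("GAT", 0.46)],
    "C": [("TGC", 0.54), ("TGT", 0.46)],
    "Q": [("CAG", 0.73), ("CAA", 0.27)],
    "E": [("GAG", 0.58), ("GAA", 0.42)],
    "G": [("GGC", 0.34), ("GGA", 0.25), ("GGG", 0.25), ("GGT", 0.16)],
    "H": [("CAC", 0.58), ("CAT", 0.42)],
    "I": [("ATC", 0.47), ("ATT", 0.36), ("ATA", 0.17)],
    "L": [("CTG", 0.40), ("CTC", 0.20), ("TTG", 0.13), ("CTT", 0.13), ("TTA", 0.07), ("CTA", 0.07)],
    "K": [("AAG", 0.57), ("AAA", 0.43)],
    "M": [("ATG", 1.0)],
    "F": [("TTC", 0.54), ("TTT", 0.46)],
    "P": [("CCC", 0.32), ("CCT", 0.29), ("CCA", 0.28), ("CCG", 0.11)],
    "S": [("AGC", 0.24), ("TCC", 0.22), ("TCT", 0.19), ("TCA", 0.15), ("AGT", 0.15), ("TCG", 0.05)],
    "T": [("ACC", 0.36), ("ACA", 0.28), ("ACT", 0.25), ("ACG", 0.11)],
    "W": [("TGG", 1.0)],
    "Y": [("TAC", 0.56), ("TAT", 0.44)],
    "V": [("GTG", 0.46), ("GTC", 0.24), ("GTT", 0.18), ("GTA", 0.12)],
}


def reverse_translate(peptide: str, codon_table: Optional[dict] = None) -> str:
    """Most-frequent-codon reverse translation of a one-letter peptide."""
    table = HUMAN_CODON_USAGE if codon_table is None else codon_table
    return "".join(_codons_for(aa, table, "top1")[0] for aa in peptide)


def _codons_for(aa: str, table: dict, mode: str) -> list:
    if aa not in table:
        raise KeyError(f"unknown amino acid {aa!r}")
    codons = [c for c, _ in table[aa]]
    if mode == "all":
        return codons
    if mode == "top2":
        return codons[:2]
    if mode == "top1":
        return codons[:1]
    raise ValueError(f"mode must be 'all' or 'top2', got {mode!r}")


def enumerate_codon_variants(
    peptide: str, mode: str = "all", codon_table: Optional[dict] = None
) -> list[str]:
    """All DNA codon variants of ``peptide`` under the given mode.

    ``all`` enumerates every codon combination; ``top2`` restricts each
    residue to its two most frequent human codons (for longer tags where
    the full space is infeasible). The result is deduplicated.
    """
    table = HUMAN_CODON_USAGE if codon_table is None else codon_table
    if not peptide:
        raise ValueError("peptide must be non-empty")
    per_residue = [_codons_for(aa, table, mode) for aa in peptide]
    seen = set()
    out = []
    for combo in itertools.product(*per_residue):
        seq = "".join(combo)
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def _predict_sequences(
    seqs: Sequence[str],
    model: TrainedModel,
    context: ScreenContext,
    site: TargetSite,
    n_background: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    inserts = [InsertSequence(id=f"v{i:05d}", written_seq=s) for i, s in enumerate(seqs)]
    designs = [make_design(ins, site) for ins in inserts]
    X = feature_matrix(designs, [context] * len(designs), n_background, seed)
    z = model.predict(X)
    return pd.DataFrame(
        {
            "sequence": list(seqs),
            "predicted_z": z,
            "polyA_terminator": [max_homopolymer_run(s, "A") >= 4 for s in seqs],
        }
    )


def rank_variants(
    variants: Sequence[str],
    model: TrainedModel,
    context: ScreenContext,
    site: TargetSite,
    n_background: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank candidate insert sequences by predicted insertion z-score.

    Variants carrying a run of >=4 adenines are flagged as Pol-III
    terminators (poorly expressed from U6 cassettes) so they can be
    filtered. Ranking is a permutation of the input: nothing is lost or
    duplicated.
    """
    if len(variants) == 0:
        raise ValueError("no variants to rank")
    if len(set(variants)) != len(variants):
        raise ValueError("variants must be unique")
    df = _predict_sequences(variants, model, context, site, n_background, seed)
    df = df.sort_values("predicted_z", ascending=False, kind="mergesort")
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)


def pad_insert(
    insert: str,
    model: TrainedModel,
    context: ScreenContext,
    site: TargetSite,
    target_len: int = 18,
    placement: str = "both-split",
    n_background: int = 1000,
    seed: int = 0,
    return_all: bool = False,
):
    """Pad a short insert to ``target_len`` with the best-predicted bases.

    Enumerates every pad of length ``target_len - len(insert)`` (4^k
    combinations, k <= 8) placed per ``placement``: ``3prime`` appends,
    ``5prime`` prepends, ``both-split`` (default) tries every split of the
    pad across both ends. Returns the top padded sequence — always
    containing the original insert as a contiguous substring — or the full
    ranked table with ``return_all``.
    """
    k = target_len - len(insert)
    if k <= 0:
        raise ValueError("target_len must exceed the insert length")
    if k > 8:
        raise ValueError("pad length > 8 nt: enumeration would exceed 4^8")
    pads = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    candidates = set()
    for pad in pads:
        if placement == "3prime":
            candidates.add(insert + pad)
        elif placement == "5prime":
            candidates.add(pad + insert)
        elif placement == "both-split":
            for i in range(k + 1):
                candidates.add(pad[:i] + insert + pad[i:])
        else:
            raise ValueError(f"unknown placement {placement!r}")
    ranked = _predict_sequences(sorted(candidates), model, context, site, n_background, seed)
    ranked = ranked.sort_values("predicted_z", ascending=False, kind="mergesort").reset_index(drop=True)
    assert all(insert in s for s in ranked["sequence"])
    if return_all:
        return ranked
    return ranked.iloc[0]["sequence"]
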