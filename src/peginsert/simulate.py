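"""Generative model of pooled prime-insertion screens.

Every pipeline stage and the predictor are testable without external data:
the generator draws an insert library, assigns each design a ground-truth
insertion efficiency from the known effect structure (length curve,
cytosine preference, reverse-transcribed-template structure, poly-A
terminator penalty, MMR length dependence), and emits either efficiency
tables with multiplicative lognormal replicate noise or flank-anchored
amplicon reads (with counting noise and rare spiked indel outcomes) that
feed straight into the screen pipeline.

Effect sizes default to the screen-derived values: +2.2% relative rate per
percentage point of cytosine, a 4.8-fold expression penalty for inserts
with >=4 consecutive adenines, and an MMR benefit of a*exp(-b*L) + 1 with
a = 25, b = 0.58 (fold change ~15 at L = 1, decaying ~44% per nt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from peginsert.core import (
    InsertSequence,
    PegRNADesign,
    ScreenContext,
    TargetSite,
    make_design,
    max_homopolymer_run,
)
from peginsert.screen import CountTable, pegrna_plasmid_flanks
from peginsert.structure import StructureContext, structure_zscore

#: Control points of the piecewise length-effect curve (log scale):
#: a short boost at 3–4 nt, a plateau at 15–21 nt, decay beyond 30 nt.
LENGTH_EFFECT_POINTS = (
    (1, 0.0),
    (2, 0.0),
    (3, np.log(2.8)),
    (4, np.log(2.8)),
    (5, 0.0),
    (14, 0.0),
    (15, np.log(1.45)),
    (21, np.log(1.45)),
    (30, 0.0),
    (45, -np.log(3.0)),
    (69, -np.log(6.0)),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth effect structure of the synthetic screens."""

    mu_log: float = float(np.log(3.0))  # baseline log percent efficiency
    beta_C: float = float(np.log(1.022))  # per percentage point of C
    beta_struct: float = -0.18  # per structure-z unit (negative z = stronger)
    mmr_a: float = 25.0
    mmr_b: float = 0.58
    polyA_factor: float = 4.8  # expression penalty for >=4 consecutive A
    noise_sd: float = 0.5  # lognormal replicate noise, log scale
    coverage: int = 1000  # reads per library member and amplicon
    abundance_sigma: float = 0.5  # lognormal plasmid abundance spread
    n_background: int = 1000  # structure z-score background sample
    structure_seed: int = 0  # background seed (shared with featurization)
    indel_rates: dict = field(
        default_factory=lambda: {
            "scaffold_integration": 0.0,
            "mutated_insertion": 0.0,
            "duplication": 0.0,
            "nick_deletion": 0.0,
            "other_deletion": 0.0,
        }
    )

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(v < 0 for v in self.indel_rates.values()):
            raise ValueError("indel rates must be >= 0")


def length_effect_log(length) -> np.ndarray:
    """Piecewise-linear log-scale length effect."""
    xs, ys = zip(*LENGTH_EFFECT_POINTS)
    return np.interp(np.asarray(length, dtype=float), xs, ys)


def mmr_ratio(length, a: float, b: float) -> np.ndarray:
    """Fold benefit of losing MMR for an insert of a given length."""
    return a * np.exp(-b * np.asarray(length, dtype=float)) + 1.0


def paper_like_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Length mixture emulating the screen library: a dense short tail
    (all 1–4-mers plus random 5–10-mers), motif-like mid lengths and
    structure-set bumps at 20/30 nt, spanning 1–69 nt."""
    choice = rng.random(n)
    lengths = np.empty(n, dtype=int)
    short = choice < 0.35
    lengths[short] = rng.integers(1, 11, size=short.sum())
    mid = (choice >= 0.35) & (choice < 0.85)
    lengths[mid] = np.clip(np.round(rng.gamma(3.0, 7.0, size=mid.sum())), 3, 69).astype(int)
    bump = choice >= 0.85
    lengths[bump] = rng.choice([18, 20, 30], size=bump.sum())
    return lengths


def simulate_library(
    n: int,
    length_distribution: int | Sequence[int] | Callable | None = None,
    seed: int = 0,
) -> list[InsertSequence]:
    """Draw ``n`` uniform-random inserts; reproducible given ``seed``.

    ``length_distribution`` may be a fixed length, an array of lengths, a
    callable ``f(rng, n) -> lengths``, or None for the screen-like mixture.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if length_distribution is None:
        lengths = paper_like_lengths(rng, n)
    elif isinstance(length_distribution, int):
        if length_distribution < 1:
            raise ValueError("fixed length must be >= 1")
        lengths = np.full(n, length_distribution, dtype=int)
    elif callable(length_distribution):
        lengths = np.asarray(length_distribution(rng, n), dtype=int)
    else:
        lengths = np.asarray(length_distribution, dtype=int)
        if len(lengths) != n:
            raise ValueError("length array must have n entries")
    if (lengths < 1).any():
        raise ValueError("lengths must be >= 1")
    bases = np.array(list("ACGT"))
    return [
        InsertSequence(
            id=f"ins{i:05d}",
            written_seq="".join(rng.choice(bases, size=L)),
            category="random",
        )
        for i, L in enumerate(lengths)
    ]


def true_efficiency(
    design: PegRNADesign,
    context: ScreenContext,
    params: GeneratorParams,
    rtt_z: Optional[float] = None,
) -> float:
    """Deterministic ground-truth percent efficiency before noise.

    log rate = baseline + length effect + beta_C*(%C − 25) + beta_struct*z
    − log(polyA penalty if >=4 consecutive A); MMR-proficient contexts are
    divided by the MMR ratio a*exp(−b*L) + 1.
    """
    seq = design.insert.written_seq
    L = len(seq)
    if rtt_z is None:
        rtt_z = structure_zscore(
            design,
            StructureContext.RTT,
            n_background=params.n_background,
            seed=params.structure_seed,
        ).value
    log_rate = (
        params.mu_log
        + float(length_effect_log(L))
        + params.beta_C * (100.0 * seq.count("C") / L - 25.0)
        + params.beta_struct * rtt_z
    )
    if max_homopolymer_run(seq, "A") >= 4:
        log_rate -= np.log(params.polyA_factor)
    if context.mmr_proficient:
        log_rate -= np.log(mmr_ratio(L, params.mmr_a, params.mmr_b))
    return float(np.exp(log_rate))


def true_efficiency_table(
    library: Sequence[InsertSequence],
    site: TargetSite,
    context: ScreenContext,
    params: GeneratorParams,
) -> pd.DataFrame:
    """Ground-truth efficiencies for a whole library at one site."""
    rows = []
    for ins in library:
        design = make_design(ins, site)
        rows.append(
            {
                "insert_id": ins.id,
                "length": len(ins),
                "true_efficiency": true_efficiency(design, context, params),
            }
        )
    return pd.DataFrame(rows)


def add_replicate_noise(
    truth: pd.DataFrame,
    params: GeneratorParams,
    context: ScreenContext,
    seed: int,
    replicate: str = "r1",
) -> pd.DataFrame:
    """Multiplicative lognormal measurement noise on true efficiencies."""
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=0.0, sigma=params.noise_sd, size=len(truth))
    return pd.DataFrame(
        {
            "insert_id": truth["insert_id"],
            "screen_id": context.screen_id,
            "replicate": replicate,
            "efficiency": truth["true_efficiency"].to_numpy() * noise,
        }
    )


def simulate_screen(
    library: Sequence[InsertSequence],
    site: TargetSite,
    context: ScreenContext,
    params: Optional[GeneratorParams] = None,
    seed: int = 0,
    emit: str = "counts",
    replicate: str = "r1",
):
    """One replicate of a pooled screen: pegRNA and target amplicons.

    Plasmid abundances are lognormal; pegRNA-amplicon counts are a
    multinomial over abundance; target-amplicon reads are a mixture of
    unedited reads, correct insertions (probability proportional to
    abundance x efficiency) and indel categories at their spike rates.

    Returns (target, pegrna, truth): two :class:`CountTable` objects (or
    lists of flank-anchored read strings with ``emit="reads"``) and the
    per-insert ground-truth table.
    """
    params = GeneratorParams() if params is None else params
    if params.coverage <= 0:
        raise ValueError("coverage must be > 0")
    if emit not in ("counts", "reads"):
        raise ValueError("emit must be 'counts' or 'reads'")
    rng = np.random.default_rng(seed)
    n = len(library)
    truth = true_efficiency_table(library, site, context, params)
    abundance = rng.lognormal(0.0, params.abundance_sigma, size=n)
    abundance /= abundance.sum()
    total = params.coverage * n

    pegrna_counts = rng.multinomial(total, abundance)

    p_edit = abundance * truth["true_efficiency"].to_numpy() / 100.0
    indel_items = list(params.indel_rates.items())
    p_indel = np.array([r for _, r in indel_items])
    p_unedited = 1.0 - p_edit.sum() - p_indel.sum()
    if p_unedited < 0:
        raise ValueError("edit + indel probabilities exceed 1; lower rates")
    draw = rng.multinomial(total, np.concatenate([p_edit, p_indel, [p_unedited]]))
    target_counts = draw[:n]
    indel_counts = dict(zip((c for c, _ in indel_items), draw[n:-1]))
    unedited = int(draw[-1])

    truth = truth.assign(
        abundance=abundance,
        pegrna_count=pegrna_counts,
        target_count=target_counts,
    )

    if emit == "counts":
        target = CountTable(
            context.screen_id, replicate, "target",
            {ins.id: int(c) for ins, c in zip(library, target_counts)},
            unmatched=int(sum(indel_counts.values())),
            unedited=unedited,
        )
        pegrna = CountTable(
            context.screen_id, replicate, "pegRNA",
            {ins.id: int(c) for ins, c in zip(library, pegrna_counts)},
        )
        return target, pegrna, truth

    target_reads = _emit_target_reads(
        library, site, target_counts, indel_counts, unedited, rng
    )
    pegrna_reads = _emit_pegrna_reads(library, site, pegrna_counts)
    return target_reads, pegrna_reads, truth


def _emit_target_reads(library, site, target_counts, indel_counts, unedited, rng):
    """Flank-anchored target-window read strings (10 up of PBS .. 60 down)."""
    prefix = site.flank_up[-23:]
    suffix = site.flank_down[:60]
    ha = site.flank_down[:34]
    reads = []
    for ins, c in zip(library, target_counts):
        reads.extend([prefix + ins.written_seq + suffix] * int(c))
    reads.extend([prefix + suffix] * unedited)
    long_inserts = [i for i in library if len(i) > 10] or list(library)
    for category, c in indel_counts.items():
        for _ in range(int(c)):
            ins = library[rng.integers(len(library))]
            if category == "scaffold_integration":
                reads.append(prefix + ins.written_seq + ha + "GCACCGACTCGG" + suffix)
            elif category == "mutated_insertion":
                src = long_inserts[rng.integers(len(long_inserts))]
                reads.append(prefix + _mutate(src.written_seq, 2, rng) + suffix)
            elif category == "duplication":
                reads.append(prefix + ha + suffix)
            elif category == "nick_deletion":
                reads.append(prefix[:-3] + suffix[3:])
            elif category == "other_deletion":
                reads.append(prefix + suffix[:40] + suffix[46:])
            else:
                raise ValueError(f"unknown indel category {category!r}")
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def _mutate(seq: str, k: int, rng) -> str:
    out = list(seq)
    positions = rng.choice(len(seq), size=min(k, len(seq)), replace=False)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _emit_pegrna_reads(library, site, pegrna_counts):
    up, down = pegrna_plasmid_flanks(site)
    reads = []
    for ins, c in zip(library, pegrna_counts):
        reads.extend([up + ins.written_seq + down] * int(c))
    return reads


def write_fastq(reads: Sequence[str], path) -> None:
    """Write read strings as FASTQ with constant quality (never consumed)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
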