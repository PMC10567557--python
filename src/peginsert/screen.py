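"""Pooled-screen read processing: counting, outcome classification, efficiencies.

Reads are pre-merged amplicon sequences (plain strings or FASTQ). Counting
is exact, ungapped matching of insert sequences flanked by fixed anchor
sequences — 10 nt of target-site sequence for the target amplicon, 15 nt of
pegRNA plasmid sequence for the pegRNA amplicon — with zero mismatches
allowed, so only insertions at the correct location are counted.

Insertion efficiency for an insert is its frequency among target-site reads
divided by its frequency among pegRNA-amplicon reads. Inserts with fewer
than 20 pegRNA-amplicon reads in any replicate are dropped from all
replicates before averaging.

Unintended outcomes are classified on reads trimmed to a fixed window
around the nick (10 nt upstream of the PBS through 60 nt downstream of the
insertion site; 83 nt for an indel-free read with a 13-nt PBS) by a
sequential decision tree; see :func:`classify_outcomes`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from peginsert.core import InsertSequence, TargetSite
from peginsert.features import length_bin_label

logger = logging.getLogger(__name__)

MIN_PEGRNA_READS = 20
TARGET_FLANK = 10
PEGRNA_FLANK = 15
#: First 5 nt of the reverse-complemented scaffold 3' end; their presence
#: directly downstream of the RT template marks a scaffold integration.
SCAFFOLD_SIGNATURE = "GCACC"


@dataclass
class CountTable:
    """Per-insert read counts for one amplicon of one replicate."""

    screen_id: str
    replicate: str
    amplicon: str  # "target" | "pegRNA"
    counts: dict
    unmatched: int = 0
    unedited: int = 0

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values()) + self.unmatched + self.unedited

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "insert_id": list(self.counts),
                "count": list(self.counts.values()),
                "screen_id": self.screen_id,
                "replicate": self.replicate,
                "amplicon": self.amplicon,
            }
        )


@dataclass(frozen=True)
class OutcomeRecord:
    """Classification of one trimmed target-amplicon read."""

    read_id: str
    category: str
    details: dict = field(default_factory=dict)


OUTCOME_CATEGORIES = (
    "library_insertion",
    "dropped",  # contains N; removed before classification
    "unedited",
    "snv_only",
    "scaffold_integration",
    "mutated_insertion",
    "duplication",
    "nick_deletion",
    "other_deletion",
    "other",
)


def read_fastq_sequences(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from an (uncompressed) FASTQ file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def _as_pairs(reads) -> list[tuple[str, str]]:
    out = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            out.append((f"read{i}", r))
        else:
            out.append((r[0], r[1]))
    return out


def _match_anchored(
    reads, library: Sequence[InsertSequence], flank_up: str, flank_down: str,
    allow_unedited: bool,
) -> tuple[dict, int, int]:
    """Exact flank+insert+flank matching. Returns (counts, unedited, unmatched)."""
    by_seq = {ins.written_seq: ins.id for ins in library}
    counts = {ins.id: 0 for ins in library}
    unedited = 0
    unmatched = 0
    n_anchorless = 0
    pairs = _as_pairs(reads)
    for _, seq in pairs:
        i = seq.find(flank_up)
        if i < 0:
            unmatched += 1
            n_anchorless += 1
            continue
        rest = seq[i + len(flank_up):]
        matched = False
        if allow_unedited and rest.startswith(flank_down):
            unedited += 1
            matched = True
        else:
            j = rest.find(flank_down)
            while j >= 0:
                ins_id = by_seq.get(rest[:j])
                if ins_id is not None:
                    counts[ins_id] += 1
                    matched = True
                    break
                j = rest.find(flank_down, j + 1)
        if not matched:
            unmatched += 1
    if pairs and n_anchorless >= 0.5 * len(pairs):
        raise ValueError(
            "upstream anchor missing in >=50% of reads — wrong target site?"
        )
    return counts, unedited, unmatched


def match_target_reads(
    reads,
    site: TargetSite,
    library: Sequence[InsertSequence],
    screen_id: str = "screen",
    replicate: str = "r1",
) -> CountTable:
    """Count library insertions in merged target-amplicon reads.

    Each insert is matched as the exact string
    ``flank_up[-10:] + insert + flank_down[:10]`` (0 mismatches); reads
    carrying the intact 20-nt window around the nick with no insert are
    counted as unedited. Everything else is unmatched.
    """
    counts, unedited, unmatched = _match_anchored(
        reads, library, site.flank_up[-TARGET_FLANK:], site.flank_down[:TARGET_FLANK],
        allow_unedited=True,
    )
    table = CountTable(screen_id, replicate, "target", counts, unmatched, unedited)
    logger.info(
        "target amplicon %s/%s: %d reads, %d matched inserts, %d unedited, %d unmatched",
        screen_id, replicate, table.total_reads, sum(counts.values()), unedited, unmatched,
    )
    return table


def pegrna_plasmid_flanks(site: TargetSite, pbs_len: int = 13) -> tuple[str, str]:
    """15-nt plasmid anchors around the insert on the pegRNA cassette.

    Read in written-strand orientation the cassette region is
    ... revcomp(PBS) | insert | homology arm ...; revcomp(PBS) equals the
    genomic upstream sequence, extended 5' with the invariant cassette
    bases (complement of the scaffold-proximal vector sequence, here the
    Pol-III terminator side) to reach 15 nt.
    """
    pad = "AAAAAA"  # terminator-side cassette bases upstream of revcomp(PBS)
    up = (pad + site.flank_up[-pbs_len:])[-PEGRNA_FLANK:]
    down = site.flank_down[:PEGRNA_FLANK]
    return up, down


def match_pegrna_reads(
    reads,
    library: Sequence[InsertSequence],
    flank_up: str,
    flank_down: str,
    screen_id: str = "screen",
    replicate: str = "r1",
) -> CountTable:
    """Count inserts in pegRNA-amplicon reads with 15-nt plasmid anchors."""
    if len(flank_up) < PEGRNA_FLANK or len(flank_down) < PEGRNA_FLANK:
        raise ValueError("pegRNA amplicon anchors must be >= 15 nt")
    counts, _, unmatched = _match_anchored(
        reads, library, flank_up[-PEGRNA_FLANK:], flank_down[:PEGRNA_FLANK],
        allow_unedited=False,
    )
    table = CountTable(screen_id, replicate, "pegRNA", counts, unmatched, 0)
    logger.info(
        "pegRNA amplicon %s/%s: %d reads, %d matched, %d unmatched",
        screen_id, replicate, table.total_reads, sum(counts.values()), unmatched,
    )
    return table


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------

def osa_distance(a: str, b: str, cutoff: Optional[int] = None) -> int:
    """Optimal string alignment (restricted Damerau–Levenshtein) distance.

    Substitutions, insertions, deletions and adjacent transpositions, with
    no substring edited twice. ``cutoff`` allows early exit; distances above
    it are returned as ``cutoff + 1``.
    """
    la, lb = len(a), len(b)
    if cutoff is not None and abs(la - lb) > cutoff:
        return cutoff + 1
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        if cutoff is not None and min(cur) > cutoff:
            return cutoff + 1
        prev2, prev = prev, cur
    return prev[lb]


def trim_window(
    reads,
    site: TargetSite,
    pbs_len: int = 13,
    window_up: int = 10,
    window_down: int = 60,
):
    """Trim reads to the classification window by anchor matching.

    The window runs from the 10 nt directly upstream of the PBS through the
    60 nt downstream of the insertion site; reads missing either anchor are
    discarded.
    """
    up_anchor = site.flank_up[-(window_up + pbs_len):-pbs_len]
    down_anchor = site.flank_down[window_down - 10: window_down]
    out = []
    for rid, seq in _as_pairs(reads):
        i = seq.find(up_anchor)
        if i < 0:
            continue
        j = seq.find(down_anchor, i)
        if j < 0:
            continue
        out.append((rid, seq[i: j + len(down_anchor)]))
    return out


def classify_outcomes(
    trimmed_reads,
    site: TargetSite,
    library: Sequence[InsertSequence],
    homology_arm: Optional[str] = None,
    pbs_len: int = 13,
    window_up: int = 10,
    window_down: int = 60,
) -> list[OutcomeRecord]:
    """Classify trimmed target-window reads into editing-outcome categories.

    Sequential decision tree, each read taking the first branch it satisfies:

    1. exact library insertion at the nick → ``library_insertion``
    2. contains N → ``dropped``
    3. intact 20-nt window around the nick → ``unedited``
    4. read has the indel-free reference length → ``snv_only``
    5. ≥5 scaffold nucleotides (GCACC) directly downstream of the RT
       template product → ``scaffold_integration``
    6. nick-site insertion within OSA distance ≤3 of a library insert
       >10 nt → ``mutated_insertion``
    7. ≥2 copies of the homology arm → ``duplication``
    8. deletion overlapping the nick ±10 nt → ``nick_deletion``
    9. any other deletion → ``other_deletion``
    10. everything else → ``other``
    """
    ha = site.flank_down[:34] if homology_arm is None else homology_arm
    prefix = site.flank_up[-(window_up + pbs_len):]
    suffix = site.flank_down[:window_down]
    reference = prefix + suffix
    ref_len = len(reference)
    nick_pos = len(prefix)
    by_seq = {ins.written_seq: ins.id for ins in library}
    long_inserts = [ins for ins in library if len(ins.written_seq) > 10]

    records = []
    for rid, seq in _as_pairs(trimmed_reads):
        records.append(
            OutcomeRecord(rid, *_classify_one(
                seq, reference, ref_len, nick_pos, prefix, suffix,
                by_seq, long_inserts, ha,
            ))
        )
    counts = outcome_counts(records)
    logger.info("classified %d reads: %s", len(records), dict(counts))
    return records


def _nick_insert_segment(seq, prefix, suffix) -> Optional[str]:
    if len(seq) > len(prefix) + len(suffix) and seq.startswith(prefix) and seq.endswith(suffix):
        return seq[len(prefix): len(seq) - len(suffix)]
    return None


def _classify_one(
    seq, reference, ref_len, nick_pos, prefix, suffix,
    by_seq, long_inserts, ha,
) -> tuple[str, dict]:
    segment = _nick_insert_segment(seq, prefix, suffix)
    if segment is not None and segment in by_seq:
        return "library_insertion", {"insert_id": by_seq[segment]}
    if "N" in seq:
        return "dropped", {}
    if seq == reference:
        return "unedited", {}
    if len(seq) == ref_len:
        return "snv_only", {}
    if segment is not None:
        k = segment.find(ha + SCAFFOLD_SIGNATURE)
        if k >= 0 or (ha + SCAFFOLD_SIGNATURE) in seq:
            return "scaffold_integration", {}
        for ins in long_inserts:
            d = osa_distance(segment, ins.written_seq, cutoff=3)
            if d <= 3:
                return "mutated_insertion", {"insert_id": ins.id, "distance": d}
    elif (ha + SCAFFOLD_SIGNATURE) in seq:
        return "scaffold_integration", {}
    if seq.count(ha) >= 2:
        return "duplication", {}
    if len(seq) < ref_len:
        del_interval = _deletion_interval(seq, reference)
        if del_interval is not None:
            lo, hi = del_interval
            if lo <= nick_pos + 10 and hi >= nick_pos - 10:
                return "nick_deletion", {"interval": (lo, hi)}
            return "other_deletion", {"interval": (lo, hi)}
    return "other", {}


def _deletion_interval(seq: str, reference: str) -> Optional[tuple[int, int]]:
    """Deleted reference interval [lo, hi) from prefix/suffix matching."""
    p = 0
    while p < len(seq) and p < len(reference) and seq[p] == reference[p]:
        p += 1
    s = 0
    while (
        s < len(seq) - p
        and s < len(reference) - p
        and seq[len(seq) - 1 - s] == reference[len(reference) - 1 - s]
    ):
        s += 1
    if p + s < len(seq):  # mismatches beyond a clean deletion
        return None if p + s == 0 else (p, len(reference) - s)
    return (p, len(reference) - s)


def outcome_counts(records: Iterable[OutcomeRecord]) -> pd.Series:
    s = pd.Series([r.category for r in records], dtype="object").value_counts()
    return s.reindex(OUTCOME_CATEGORIES, fill_value=0)


# ---------------------------------------------------------------------------
# SNV profiling
# ---------------------------------------------------------------------------

def snv_profile(
    trimmed_reads,
    site: TargetSite,
    pbs_len: int = 13,
    window_up: int = 10,
    window_down: int = 60,
) -> tuple[pd.DataFrame, float]:
    """Per-position substitution rates over indel-free trimmed reads.

    Positions are reported as 1-based offsets from the nick (negative
    upstream). Reads not matching the indel-free reference length are
    skipped. Non-reference nucleotides count as mutations except a known
    variant allele (e.g. a +9 SNP), whose frequency is returned separately
    rather than being called a mutation.
    """
    prefix = site.flank_up[-(window_up + pbs_len):]
    suffix = site.flank_down[:window_down]
    reference = prefix + suffix
    ref_len = len(reference)
    offsets = list(range(-len(prefix), 0)) + list(range(1, len(suffix) + 1))
    counts = np.zeros((ref_len, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    n_used = 0
    for _, seq in _as_pairs(trimmed_reads):
        if len(seq) != ref_len or "N" in seq:
            continue
        n_used += 1
        for i, b in enumerate(seq):
            counts[i, base_idx[b]] += 1
    kv = site.known_variant
    rows = []
    variant_freq = float("nan")
    for i, off in enumerate(offsets):
        ref_base = reference[i]
        total = counts[i].sum()
        nonref = total - counts[i, base_idx[ref_base]]
        excluded = 0
        if kv is not None and off == kv.position:
            excluded = counts[i, base_idx[kv.alt]]
            variant_freq = excluded / total if total else float("nan")
        rate = (nonref - excluded) / total if total else 0.0
        rows.append(
            {
                "offset": off,
                "ref": ref_base,
                **{b: counts[i, j] for b, j in base_idx.items()},
                "mutation_rate": rate,
            }
        )
    logger.info("snv profile over %d indel-free reads", n_used)
    return pd.DataFrame(rows), variant_freq


# ---------------------------------------------------------------------------
# Efficiencies and normalization
# ---------------------------------------------------------------------------

def compute_efficiencies(
    target: CountTable,
    pegrna: CountTable,
    min_reads: int = MIN_PEGRNA_READS,
) -> pd.DataFrame:
    """Per-insert insertion efficiency for one replicate.

    efficiency_i = (target_i / target_total) / (pegrna_i / pegrna_total),
    after dropping inserts with fewer than ``min_reads`` pegRNA-amplicon
    reads. Frequencies are over all reads in the amplicon.
    """
    keep = [i for i, c in pegrna.counts.items() if c >= min_reads]
    t_tot, p_tot = target.total_reads, pegrna.total_reads
    if t_tot == 0 or p_tot == 0:
        raise ValueError("empty count table")
    rows = [
        {
            "insert_id": i,
            "screen_id": target.screen_id,
            "replicate": target.replicate,
            "efficiency": (target.counts.get(i, 0) / t_tot) / (pegrna.counts[i] / p_tot),
        }
        for i in keep
    ]
    return pd.DataFrame(rows, columns=["insert_id", "screen_id", "replicate", "efficiency"])


def combine_replicates(
    pairs: Sequence[tuple[CountTable, CountTable]],
    min_reads: int = MIN_PEGRNA_READS,
) -> pd.DataFrame:
    """Efficiencies across replicates with the any-replicate read filter.

    An insert failing ``min_reads`` on the pegRNA amplicon in *any*
    replicate is removed from all replicates. Returns the long per-replicate
    table; average with :func:`average_replicates`.
    """
    drop: set = set()
    for _, pegrna in pairs:
        drop |= {i for i, c in pegrna.counts.items() if c < min_reads}
    frames = []
    for target, pegrna in pairs:
        eff = compute_efficiencies(target, pegrna, min_reads=min_reads)
        frames.append(eff[~eff["insert_id"].isin(drop)])
    return pd.concat(frames, ignore_index=True)


def average_replicates(eff: pd.DataFrame) -> pd.DataFrame:
    """Mean efficiency per (insert, screen) over replicates."""
    out = (
        eff.groupby(["insert_id", "screen_id"], as_index=False)["efficiency"]
        .mean()
    )
    return out


def merge_sets(set1: pd.DataFrame, set2: pd.DataFrame) -> pd.DataFrame:
    """Merge two library sets onto a common efficiency scale.

    Set 2 efficiencies are multiplied by
    mean(shared inserts in Set 1) / mean(shared inserts in Set 2); shared
    inserts are then reported as the mean of the two (rescaled) sets.
    Inputs are replicate-averaged tables with insert_id and efficiency.
    """
    shared = set(set1["insert_id"]) & set(set2["insert_id"])
    if not shared:
        raise ValueError("no shared inserts between sets")
    m1 = set1[set1["insert_id"].isin(shared)]["efficiency"].mean()
    m2 = set2[set2["insert_id"].isin(shared)]["efficiency"].mean()
    scale = m1 / m2
    logger.info("merging sets: %d shared inserts, scale factor %.4f", len(shared), scale)
    s2 = set2.copy()
    s2["efficiency"] = s2["efficiency"] * scale
    merged = pd.concat([set1, s2], ignore_index=True)
    return (
        merged.groupby("insert_id", as_index=False)
        .agg({c: ("mean" if c == "efficiency" else "first") for c in merged.columns if c != "insert_id"})
    )


def length_normalize(eff: pd.DataFrame, lengths: dict) -> pd.DataFrame:
    """Add a ``length_relative`` column: efficiency / same-length(-bin) median.

    Inserts shorter than 10 nt are normalized against the median of their
    exact length; longer ones against their length bin (10–14, 15–19,
    20–24, 25–29, 30–39, 40–49, 50–59, 60–69).
    """
    out = eff.copy()
    out["length"] = out["insert_id"].map(lengths)
    if out["length"].isna().any():
        missing = out.loc[out["length"].isna(), "insert_id"].unique()
        raise KeyError(f"no length for inserts: {list(missing)[:5]}")
    out["length_bin"] = out["length"].astype(int).map(length_bin_label)
    med = out.groupby("length_bin")["efficiency"].transform("median")
    out["length_relative"] = out["efficiency"] / med
    return out.drop(columns=["length"])


def zscore_normalize(eff: pd.DataFrame, value: str = "efficiency") -> pd.DataFrame:
    """z-score the ``value`` column within each (screen, replicate) group.

    Uses the population standard deviation (groups are whole screens);
    raises on groups with zero variance or fewer than two inserts.
    """
    keys = [k for k in ("screen_id", "replicate") if k in eff.columns]
    out = eff.copy()

    def _z(x: pd.Series) -> pd.Series:
        if len(x) < 2:
            raise ValueError("need >= 2 inserts per screen/replicate group")
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError("zero variance in a screen/replicate group")
        return (x - x.mean()) / sd

    out["zscore"] = out.groupby(keys)[value].transform(_z)
    return out


def run_report(
    tables: Sequence[CountTable], outcome_records=None, path=None
) -> dict:
    """JSON-able processing summary: totals, match rates, outcome counts."""
    report = {
        "amplicons": [
            {
                "screen_id": t.screen_id,
                "replicate": t.replicate,
                "amplicon": t.amplicon,
                "total_reads": t.total_reads,
                "matched": int(sum(t.counts.values())),
                "unedited": t.unedited,
                "unmatched": t.unmatched,
                "match_rate": (sum(t.counts.values()) + t.unedited) / t.total_reads
                if t.total_reads
                else float("nan"),
            }
            for t in tables
        ]
    }
    if outcome_records is not None:
        report["outcomes"] = outcome_counts(outcome_records).to_dict()
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
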