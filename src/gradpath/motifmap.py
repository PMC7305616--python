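"""Positional motif maps and binding-proximity analysis around cassette exons.

Splicing regulators act position-specifically near the exons they control,
so a candidate regulator's binding motif should occur more often at
particular offsets from the splice sites of regulated exons than of
non-regulated ones. This module classifies events into regulated /
non-regulated sets from a delta-PSI table, builds per-position motif
frequency tracks over splice-site-anchored regions (smoothed with a running
mean for display), locates significantly different windows with sliding
Fisher's exact tests, and counts crosslink-tag (CLIP) proximity per event
set as orthogonal evidence of direct binding.

Anchored regions per event: the last L nt of the upstream intron (anchored
at the cassette 3' splice site), the cassette exon itself (5'->3'), and the
first L nt of the downstream intron (anchored at the 5' splice site).
Upstream tracks are right-aligned at their anchor; exon and downstream
tracks are left-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import fisher_exact

__all__ = [
    "REGIONS",
    "A1CF_MOTIFS",
    "RegionSequenceSet",
    "EventSets",
    "MotifTrack",
    "classify_events",
    "motif_frequency",
    "smooth",
    "window_fisher",
    "clip_proximity",
]

REGIONS = ("upstream_intron", "exon", "downstream_intron")

# A/U-rich 3-mers bound by the A1CF RNA-binding protein
A1CF_MOTIFS = frozenset({"AAU", "UAA", "AUU"})

_RIGHT_ALIGNED = {"upstream_intron"}


def _to_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


@dataclass
class RegionSequenceSet:
    """Per-event anchored sequences for each region, as uppercase RNA."""

    sequences: dict[str, dict[str, str]]  # region -> event_id -> sequence

    def __post_init__(self):
        for region in self.sequences:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
            self.sequences[region] = {
                ev: _to_rna(s) for ev, s in self.sequences[region].items()
            }

    @property
    def events(self) -> set[str]:
        out: set[str] = set()
        for seqs in self.sequences.values():
            out |= set(seqs)
        return out

    def region_length(self, region: str) -> int:
        seqs = self.sequences.get(region, {})
        return max((len(s) for s in seqs.values()), default=0)

    def subset(self, event_ids: Iterable[str]) -> "RegionSequenceSet":
        keep = set(event_ids)
        return RegionSequenceSet(
            {
                region: {ev: s for ev, s in seqs.items() if ev in keep}
                for region, seqs in self.sequences.items()
            }
        )

    def to_fasta(self, file: str | Path) -> None:
        records = []
        for region, seqs in self.sequences.items():
            for ev, s in seqs.items():
                records.append(
                    SeqRecord(Seq(s), id=f"{ev}|{region}|{len(s)}", description="")
                )
        SeqIO.write(records, str(file), "fasta")

    @classmethod
    def from_fasta(cls, file: str | Path) -> "RegionSequenceSet":
        sequences: dict[str, dict[str, str]] = {}
        for rec in SeqIO.parse(str(file), "fasta"):
            ev, region, _length = rec.id.split("|")
            sequences.setdefault(region, {})[ev] = str(rec.seq)
        return cls(sequences)


@dataclass
class EventSets:
    """Disjoint regulated/non-regulated event-ID sets with their thresholds."""

    regulated_included: set[str]
    regulated_excluded: set[str]
    non_regulated: set[str]
    reg_threshold: float = 10.0
    nonreg_threshold: float = 5.0

    def __post_init__(self):
        sets = [self.regulated_included, self.regulated_excluded, self.non_regulated]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("event sets must be pairwise disjoint")

    @property
    def regulated(self) -> set[str]:
        return self.regulated_included | self.regulated_excluded

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "regulated_included": self.regulated_included,
            "regulated_excluded": self.regulated_excluded,
            "non_regulated": self.non_regulated,
        }


def classify_events(
    dpsi_table: pd.DataFrame,
    reg_threshold: float = 10.0,
    nonreg_threshold: float = 5.0,
) -> EventSets:
    """Split events into regulated and non-regulated sets by delta-PSI.

    ``dpsi_table`` columns: event, junction, dpsi_percent, role
    (inclusion|exclusion), with delta-PSI in percent. An event is regulated
    when both an inclusion and an exclusion junction reach
    |dPSI| >= reg_threshold, split by the sign of its inclusion junction;
    non-regulated when every junction stays below nonreg_threshold. Events
    between thresholds are left unassigned.
    """
    required = {"event", "junction", "dpsi_percent", "role"}
    if not required <= set(dpsi_table.columns):
        raise ValueError(f"dpsi table must have columns {sorted(required)}")
    bad_roles = set(dpsi_table["role"]) - {"inclusion", "exclusion"}
    if bad_roles:
        raise ValueError(f"malformed junction role(s): {sorted(bad_roles)}")
    vals = dpsi_table["dpsi_percent"].to_numpy(dtype=float)
    if np.any(np.abs(vals) > 100):
        raise ValueError("dpsi_percent must lie in [-100, 100]")

    inc, exc, non = set(), set(), set()
    for event, grp in dpsi_table.groupby("event"):
        d = grp["dpsi_percent"].to_numpy(dtype=float)
        roles = grp["role"].to_numpy()
        inc_hit = np.abs(d[roles == "inclusion"]) >= reg_threshold
        exc_hit = np.abs(d[roles == "exclusion"]) >= reg_threshold
        if inc_hit.any() and exc_hit.any():
            inc_d = d[roles == "inclusion"]
            top = inc_d[np.argmax(np.abs(inc_d))]
            (inc if top > 0 else exc).add(str(event))
        elif np.all(np.abs(d) < nonreg_threshold):
            non.add(str(event))
    return EventSets(inc, exc, non, reg_threshold, nonreg_threshold)


def _aligned_motif_hits(
    seqs: Mapping[str, str], motifs: Sequence[str], length: int, right: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position occurrence and coverage counts on the aligned axis."""
    k = len(next(iter(motifs)))
    hits = np.zeros(length)
    cover = np.zeros(length)
    motifs = set(motifs)
    for s in seqs.values():
        l = len(s)
        offset = length - l if right else 0
        n_starts = max(0, l - k + 1)
        cover[offset : offset + n_starts] += 1
        for j in range(n_starts):
            if s[j : j + k] in motifs:
                hits[offset + j] += 1
    return hits, cover


@dataclass
class MotifTrack:
    """Per-position motif start frequency on an anchored region."""

    region: str
    frequency: np.ndarray  # occurrences / covering events, nan where uncovered
    coverage: np.ndarray
    smoothed: np.ndarray | None = None

    def positions(self) -> np.ndarray:
        """1-based offsets from the anchor (negative upstream of a 3' ss)."""
        n = len(self.frequency)
        if self.region in _RIGHT_ALIGNED:
            return np.arange(-n, 0)
        return np.arange(1, n + 1)


def motif_frequency(
    regions: RegionSequenceSet,
    motifs: Sequence[str] = tuple(A1CF_MOTIFS),
    smooth_width: int | None = None,
) -> dict[str, MotifTrack]:
    """Fraction of events with a motif starting at each anchored position.

    An event counts once per position if any of the motifs starts there;
    the denominator is the number of events whose sequence covers that
    start position. Optionally attaches a running-mean smoothed track.
    """
    motifs = [_to_rna(m) for m in motifs]
    if not regions.events:
        raise ValueError("empty region sequence set")
    tracks = {}
    for region, seqs in regions.sequences.items():
        if not seqs:
            continue
        L = regions.region_length(region)
        hits, cover = _aligned_motif_hits(
            seqs, motifs, L, right=region in _RIGHT_ALIGNED
        )
        with np.errstate(invalid="ignore"):
            freq = np.where(cover > 0, hits / np.maximum(cover, 1), np.nan)
        track = MotifTrack(region, freq, cover)
        if smooth_width:
            track.smoothed = smooth(freq, smooth_width)
        tracks[region] = track
    return tracks


def smooth(track: np.ndarray, width: int = 20) -> np.ndarray:
    """Centered running mean with truncated windows at the boundaries."""
    if width < 1:
        raise ValueError("width must be >= 1")
    x = np.asarray(track, dtype=float)
    n = len(x)
    if width > n:
        return np.full(n, np.nanmean(x))
    out = np.empty(n)
    half_lo = (width - 1) // 2
    half_hi = width // 2
    for i in range(n):
        lo, hi = max(0, i - half_lo), min(n, i + half_hi + 1)
        window = x[lo:hi]
        out[i] = np.nanmean(window) if np.any(np.isfinite(window)) else np.nan
    return out


def window_fisher(
    setA: RegionSequenceSet,
    setB: RegionSequenceSet,
    motifs: Sequence[str] = tuple(A1CF_MOTIFS),
    window: int = 20,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Sliding-window Fisher tests of motif presence between two event sets.

    At each window start (stride 1 nt) the 2x2 table counts events that do
    or do not contain a motif start inside the window, per set; the
    two-tailed exact p is reported at the window center. No multiplicity
    correction is applied across windows — overlapping windows are strongly
    dependent and the tracks are read as a positional profile.
    """
    motifs = [_to_rna(m) for m in motifs]
    if not setA.events or not setB.events:
        raise ValueError("both event sets must be non-empty")
    k = len(motifs[0])
    out = {}
    for region in REGIONS:
        seqsA = setA.sequences.get(region, {})
        seqsB = setB.sequences.get(region, {})
        if not seqsA or not seqsB:
            continue
        L = max(setA.region_length(region), setB.region_length(region))
        right = region in _RIGHT_ALIGNED
        rows = []
        for start in range(0, L - window + 1):
            counts = []
            for seqs in (seqsA, seqsB):
                with_motif = 0
                for s in seqs.values():
                    l = len(s)
                    offset = L - l if right else 0
                    j0 = max(0, start - offset)
                    j1 = min(l - k + 1, start + window - offset)
                    if any(s[j : j + k] in motifs for j in range(j0, j1)):
                        with_motif += 1
                counts.append((with_motif, len(seqs) - with_motif))
            (a, b), (c, d) = counts
            p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
            rows.append(
                {
                    "window_start": start,
                    "center": start + window // 2,
                    "with_motif_A": a,
                    "with_motif_B": c,
                    "n_A": a + b,
                    "n_B": c + d,
                    "p": p,
                    "minus_log10_p": float(-np.log10(max(p, 1e-320))),
                    "significant": p < alpha,
                }
            )
        out[region] = pd.DataFrame(rows)
    return out


def clip_proximity(
    tags: pd.DataFrame,
    events: pd.DataFrame,
    event_sets: EventSets | Mapping[str, set[str]],
    up: int = 300,
    down: int = 300,
    min_tags: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crosslink-tag proximity per event set with pairwise Fisher tests.

    ``tags``: BED-like table (chrom, start, end, tag_count) of T-to-C
    transition sites; sites supported by fewer than ``min_tags`` unique tags
    are discarded. ``events``: per-event exon coordinates (event, chrom,
    exon_start, exon_end), 0-based half-open. An event is bound when a
    retained site starts in the upstream window, the exon, or the
    downstream window; each region is also reported separately. Returns the
    per-set bound-fraction table and the pairwise two-tailed Fisher p-value
    matrix on overall bound/unbound counts.
    """
    req_t = {"chrom", "start", "end", "tag_count"}
    req_e = {"event", "chrom", "exon_start", "exon_end"}
    if not req_t <= set(tags.columns) or not req_e <= set(events.columns):
        raise ValueError("tags/events tables missing required columns")
    if np.any(events["exon_end"].to_numpy() < events["exon_start"].to_numpy()):
        raise ValueError("negative-width exon interval; check coordinate system")

    kept = tags[tags["tag_count"] >= min_tags]
    sites: dict[str, np.ndarray] = {
        str(chrom): np.sort(grp["start"].to_numpy(dtype=int))
        for chrom, grp in kept.groupby("chrom")
    }

    def any_in(chrom: str, lo: int, hi: int) -> bool:
        pos = sites.get(chrom)
        if pos is None or hi <= lo:
            return False
        i = np.searchsorted(pos, lo, side="left")
        return i < len(pos) and pos[i] < hi

    bound: dict[str, dict[str, bool]] = {}
    for _, row in events.iterrows():
        ev, chrom = str(row["event"]), str(row["chrom"])
        s, e = int(row["exon_start"]), int(row["exon_end"])
        regions = {
            "upstream": any_in(chrom, s - up, s),
            "exon": any_in(chrom, s, e),
            "downstream": any_in(chrom, e, e + down),
        }
        regions["any"] = any(regions.values())
        bound[ev] = regions

    set_map = event_sets.as_dict() if isinstance(event_sets, EventSets) else dict(event_sets)
    rows = []
    counts = {}
    for name, ids in set_map.items():
        members = [ev for ev in ids if ev in bound]
        n = len(members)
        n_any = sum(bound[ev]["any"] for ev in members)
        counts[name] = (n_any, n - n_any)
        rows.append(
            {
                "set": name,
                "n_events": n,
                "frac_upstream": np.mean([bound[ev]["upstream"] for ev in members]) if n else np.nan,
                "frac_exon": np.mean([bound[ev]["exon"] for ev in members]) if n else np.nan,
                "frac_downstream": np.mean([bound[ev]["downstream"] for ev in members]) if n else np.nan,
                "frac_any": n_any / n if n else np.nan,
            }
        )
    fractions = pd.DataFrame(rows).set_index("set")
    names = list(set_map)
    P = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            table = [list(counts[a]), list(counts[b])]
            p = float(fisher_exact(table, alternative="two-sided")[1])
            P.loc[a, b] = P.loc[b, a] = p
    return fractions, P
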