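"""Consensus filtering of copy-number variant calls.

Retains CNVs supported by at least two independent callers, longer than
100 kb, and annotates trio inheritance and overlap with known
disease-associated loci.  Intervals are half-open 0-based internally
(BED convention) and reported 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

COPY_STATES = {"deletion", "duplication"}


@dataclass(frozen=True)
class CnvCall:
    chrom: str
    start: int  # 0-based half-open
    end: int
    copy_state: str
    individual: str
    caller: str
    supporting_callers: tuple = ()
    inheritance: str | None = None
    known_loci: tuple = ()

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")
        if self.copy_state not in COPY_STATES:
            raise ValueError(f"copy_state must be one of {COPY_STATES}: {self.copy_state}")

    @property
    def length(self) -> int:
        return self.end - self.start


def reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    """Overlap length divided by the longer interval's length; 0 when the
    calls are disjoint or on different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / max(a.length, b.length)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def consensus_calls(
    callsets,
    min_methods: int = 2,
    min_length: int = 100_000,
    ro_threshold: float = 0.5,
) -> list[CnvCall]:
    """Merge per-caller CNV lists into consensus calls.

    Calls cluster by single linkage on reciprocal overlap >= ``ro_threshold``
    (``0`` means any overlap) within each individual and copy state.  A
    cluster survives when it is supported by >= ``min_methods`` distinct
    callers and its merged span (outer bounds of the supporting calls)
    strictly exceeds ``min_length``.  Deterministic and idempotent.
    """
    calls: list[CnvCall] = []
    for cs in callsets:
        calls.extend(cs)
    calls.sort(key=lambda c: (c.individual, c.copy_state, c.chrom, c.start, c.end, c.caller))
    out: list[CnvCall] = []
    groups: dict = {}
    for c in calls:
        groups.setdefault((c.individual, c.copy_state, c.chrom), []).append(c)
    for key in sorted(groups):
        grp = groups[key]
        uf = _UnionFind(len(grp))
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                ro = reciprocal_overlap(grp[i], grp[j])
                if ro > 0 and ro >= ro_threshold:
                    uf.union(i, j)
        clusters: dict = {}
        for i in range(len(grp)):
            clusters.setdefault(uf.find(i), []).append(grp[i])
        for root in sorted(clusters):
            members = clusters[root]
            callers = sorted({m.caller for m in members})
            start = min(m.start for m in members)
            end = max(m.end for m in members)
            if len(callers) >= min_methods and (end - start) > min_length:
                out.append(
                    CnvCall(
                        chrom=members[0].chrom,
                        start=start,
                        end=end,
                        copy_state=members[0].copy_state,
                        individual=members[0].individual,
                        caller="consensus",
                        supporting_callers=tuple(callers),
                    )
                )
    out.sort(key=lambda c: (c.individual, c.chrom, c.start, c.end, c.copy_state))
    return out


def annotate_inheritance(call: CnvCall, parental_callsets: dict, ro_threshold: float = 0.5) -> CnvCall:
    """Label a child call de novo / inherited:parent / unknown.

    ``parental_callsets`` maps parent label ('mother'/'father') to that
    parent's CNV calls; a parent present with an empty list was assayed and
    carries nothing.  Inherited requires a same-state parental call at
    reciprocal overlap >= ``ro_threshold``; with both parents assayed and no
    such call the child call is de novo; without parental data: unknown.
    """
    if not parental_callsets:
        return replace(call, inheritance="unknown")
    for parent in sorted(parental_callsets):
        for pc in parental_callsets[parent]:
            if pc.copy_state == call.copy_state and reciprocal_overlap(call, pc) >= max(
                ro_threshold, 1e-12
            ):
                return replace(call, inheritance=f"inherited:{parent}")
    if {"mother", "father"} <= set(parental_callsets):
        return replace(call, inheritance="de_novo")
    return replace(call, inheritance="unknown")


def overlap_known_loci(calls, loci) -> list[CnvCall]:
    """Annotate calls overlapping named loci (any overlap).

    ``loci`` is an iterable of (chrom, start, end, name) with half-open
    0-based coordinates.
    """
    loci = list(loci)
    for chrom, start, end, name in loci:
        if end <= start:
            raise ValueError(f"malformed locus {name}: [{start}, {end})")
    annotated = []
    for c in calls:
        hits = tuple(
            name
            for chrom, start, end, name in loci
            if chrom == c.chrom and min(c.end, end) - max(c.start, start) > 0
        )
        annotated.append(replace(c, known_loci=hits) if hits else c)
    return annotated


# ---------------------------------------------------------------- I/O


def read_caller_bed(path) -> list[CnvCall]:
    """Read one caller's BED-like TSV: chrom, start, end, state, individual, caller."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "state", "individual", "caller"],
        dtype={"chrom": str, "individual": str, "caller": str},
        comment="#",
    )
    return [
        CnvCall(
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            copy_state=r.state,
            individual=r.individual,
            caller=r.caller,
        )
        for r in df.itertuples()
    ]


def consensus_to_frame(calls) -> pd.DataFrame:
    """Consensus calls as a report table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start_1based": [c.start + 1 for c in calls],
            "end_1based": [c.end for c in calls],
            "length": [c.length for c in calls],
            "copy_state": [c.copy_state for c in calls],
            "individual": [c.individual for c in calls],
            "callers": [",".join(c.supporting_callers) for c in calls],
            "inheritance": [c.inheritance or "" for c in calls],
            "known_loci": [",".join(c.known_loci) for c in calls],
        }
    )
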