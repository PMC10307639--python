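"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools

import pytest

from chromobal import Breakend, CNSegment, GenomeBuild, make_sv
from chromobal.clustering import SVCluster


@pytest.fixture
def toy_genome() -> GenomeBuild:
    return GenomeBuild.from_dict(
        {"chr1": 100_000_000, "chr5": 100_000_000, "chrY": 57_227_415}
    )


def intra_sv(uid, start, end, chrom="chrY", sides=("+", "-")):
    """Intrachromosomal SV with the given footprint (default DEL-type)."""
    return make_sv(
        uid, Breakend(chrom, int(start), sides[0]), Breakend(chrom, int(end), sides[1])
    )


def cluster_of(footprints, chrom="chrY"):
    return SVCluster(
        chrom, [intra_sv(f"sv{i}", s, e, chrom) for i, (s, e) in enumerate(footprints)]
    )


def flat_cn(chrom="chrY", length=57_227_415, cn=1):
    return [CNSegment(chrom, 0, length, cn)]


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_components(footprints, gap_max):
    """O(n^2) pairwise linkage + union-find over footprint indices."""
    n = len(footprints)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        s1, e1 = footprints[i]
        for j in range(i + 1, n):
            s2, e2 = footprints[j]
            if max(s1, s2) - min(e1, e2) <= gap_max:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(sorted(c) for c in comps.values())


def brute_force_modal(segments):
    """Per-base mode of total CN with ties toward the lower value."""
    counts = {}
    for seg in segments:
        for base in range(seg.start, seg.end):
            counts[seg.total_cn] = counts.get(seg.total_cn, 0) + 1
    best = max(counts.values())
    return min(cn for cn, c in counts.items() if c == best)


def brute_force_oscillation(values):
    """Longest contiguous sub-run of merged CN values alternating between
    exactly two states, by enumeration of all sub-runs."""
    merged = [v for i, v in enumerate(values) if i == 0 or v != values[i - 1]]
    best = 0
    for i in range(len(merged)):
        for j in range(i, len(merged)):
            run = merged[i : j + 1]
            if len(set(run)) <= 2 and all(
                run[k] != run[k + 1] for k in range(len(run) - 1)
            ):
                best = max(best, len(run))
    return best


def string_reconstruction_classes(derivative, reference_length):
    """Junction classes read directly off the reconstructed derivative string.

    The reference is a sequence of unique symbols (its positions), so the
    derivative string determines the fragment layout unambiguously. The
    string is decomposed into maximal collinear runs (consecutive positions
    +1 = forward, -1 = reverse) and each run boundary yields one junction,
    classified from first principles on the side convention.
    """
    from chromobal import classify_sv_type

    # strand-aware string: forward base i -> ("F", i); a reversed fragment is
    # its reverse complement, emitting ("R", i) in descending order
    seq: list[tuple[str, int]] = []
    for frag in derivative:
        pos = range(frag.ref_start, frag.ref_end)
        if frag.orientation == "forward":
            seq.extend(("F", p) for p in pos)
        else:
            seq.extend(("R", p) for p in reversed(pos))
    assert max(p for _, p in seq) < reference_length
    # maximal collinear runs as (ref_start, ref_end, orientation)
    runs = []
    i = 0
    while i < len(seq):
        strand, start = seq[i]
        step = 1 if strand == "F" else -1
        j = i + 1
        while j < len(seq) and seq[j] == (strand, seq[j - 1][1] + step):
            j += 1
        last = seq[j - 1][1]
        if strand == "F":
            runs.append((start, last + 1, "forward"))
        else:
            runs.append((last, start + 1, "reverse"))
        i = j
    classes = []
    for (s1, e1, o1), (s2, e2, o2) in zip(runs, runs[1:]):
        b1 = Breakend("chrT", e1, "+") if o1 == "forward" else Breakend("chrT", s1, "-")
        b2 = Breakend("chrT", s2, "-") if o2 == "forward" else Breakend("chrT", e2, "+")
        classes.append(classify_sv_type(b1, b2))
    return classes


def enumerate_derivatives(fragments):
    """All permutations x orientation assignments of a fragment list."""
    from dataclasses import replace

    n = len(fragments)
    for perm in itertools.permutations(range(n)):
        for mask in itertools.product(("forward", "reverse"), repeat=n):
            yield [replace(fragments[i], orientation=o) for i, o in zip(perm, mask)]
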