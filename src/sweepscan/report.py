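"""Chromosome-wide significance calling, cluster detection and reports.

Significance is empirical throughout: a locus's score is ranked within
a background distribution of the same statistic (chromosome-wide for
the haplotype and XP-CLR scans, genome-wide and MAF-binned for F_ST)
with the add-one rule p = (1 + #{background >= observed}) / (N + 1),
ties counted inclusively, so p is never zero and p = 1 is attainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ScoreTrack

__all__ = [
    "SignificanceCluster",
    "empirical_p",
    "find_clusters",
    "intersect_clusters",
    "render_report",
]


@dataclass
class SignificanceCluster:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    test: str
    members: list[int] = field(default_factory=list)  # member positions
    min_p: float = 1.0
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("cluster start after end")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def empirical_p(track: ScoreTrack, background: ScoreTrack, tail: str = "high") -> ScoreTrack:
    """Rank-based empirical p-values against a background track.

    ``tail='high'`` ranks the score itself; ``tail='abs'`` ranks the
    absolute value (the default choice for iHS, where both extremes are
    meaningful).
    """
    bg = background.score[np.isfinite(background.score)]
    if bg.size == 0:
        raise ValueError("empty background")
    obs = track.score.copy()
    if tail == "abs":
        bg = np.abs(bg)
        obs = np.abs(obs)
    elif tail != "high":
        raise ValueError(f"unknown tail {tail!r}")
    bg = np.sort(bg)
    p = np.full(len(track), np.nan)
    fin = np.isfinite(obs)
    n_ge = bg.size - np.searchsorted(bg, obs[fin], side="left")
    p[fin] = (1.0 + n_ge) / (bg.size + 1.0)
    return ScoreTrack(
        test=track.test, level=track.level, chrom=track.chrom, pos=track.pos,
        score=track.score, ids=track.ids, p=p, maf=track.maf,
    )


def find_clusters(
    track: ScoreTrack, threshold: float = 0.01, max_gap: int = 100_000, pad: int = 0
) -> list[SignificanceCluster]:
    """Maximal runs of sub-threshold loci with gaps <= max_gap bp.

    Singleton clusters are allowed; the cluster span runs from the first
    to the last member position, extended by ``pad`` bp on each side —
    useful for gridded statistics whose value at a point summarizes a
    window (pass half the window width).
    """
    if track.p is None:
        raise ValueError("track has no p-values")
    sig = np.nonzero(np.nan_to_num(track.p, nan=1.0) < threshold)[0]
    clusters: list[SignificanceCluster] = []
    if sig.size == 0:
        return clusters
    run = [sig[0]]
    for idx in sig[1:]:
        if track.pos[idx] - track.pos[run[-1]] <= max_gap:
            run.append(idx)
        else:
            clusters.append(_as_cluster(track, run, pad))
            run = [idx]
    clusters.append(_as_cluster(track, run, pad))
    return clusters


def _as_cluster(track: ScoreTrack, run: list[int], pad: int = 0) -> SignificanceCluster:
    return SignificanceCluster(
        chrom=track.chrom,
        start=max(1, int(track.pos[run[0]]) - pad),
        end=int(track.pos[run[-1]]) + pad,
        test=track.test,
        members=[int(track.pos[i]) for i in run],
        min_p=float(np.nanmin(track.p[run])),
    )


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    tests: list[str]
    min_p: float

    @property
    def n_tests(self) -> int:
        return len(self.tests)


def intersect_clusters(cluster_lists: list[list[SignificanceCluster]]) -> list[CandidateRegion]:
    """Interval intersections across tests, ranked by support then min p.

    Every pairwise-or-deeper overlap among clusters from different tests
    becomes a candidate; containment of the same interval by more tests
    ranks it higher.
    """
    if len(cluster_lists) < 2:
        raise ValueError("need cluster lists from >= 2 tests")
    flat = [c for lst in cluster_lists for c in lst]
    candidates: dict[tuple[int, int], CandidateRegion] = {}

    def add(start, end, members):
        tests = sorted({c.test for c in members})
        if len(tests) < 2:
            return
        key = (start, end)
        mp = min(c.min_p for c in members)
        cur = candidates.get(key)
        if cur is None or len(tests) > cur.n_tests or mp < cur.min_p:
            candidates[key] = CandidateRegion(members[0].chrom, start, end, tests, mp)

    n = len(flat)
    # grow overlap groups greedily from every pair
    for i in range(n):
        for j in range(i + 1, n):
            a, b = flat[i], flat[j]
            if a.test == b.test or a.chrom != b.chrom:
                continue
            start, end = max(a.start, b.start), min(a.end, b.end)
            if start > end:
                continue
            group = [a, b]
            for k in range(n):
                c = flat[k]
                if c is a or c is b or c.test in {g.test for g in group}:
                    continue
                s2, e2 = max(start, c.start), min(end, c.end)
                if s2 <= e2:
                    start, end = s2, e2
                    group.append(c)
            add(start, end, group)
    out = sorted(candidates.values(), key=lambda c: (-c.n_tests, c.min_p, c.start))
    return out


def render_report(
    tracks: list[ScoreTrack],
    clusters: list[list[SignificanceCluster]],
    out_prefix,
    dprime: np.ndarray | None = None,
    dprime_positions: np.ndarray | None = None,
    genes: list[tuple[str, int, int]] | None = None,
    hotspots: list[int] | None = None,
):
    """-log10(p) panel figure, cluster table TSV and candidate BED.

    Returns the paths written.  Plotting uses the non-interactive Agg
    backend; genes/hotspots are drawn if provided (never fetched).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd
    from pathlib import Path

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    chroms = {t.chrom for t in tracks}
    if len(chroms) > 1:
        raise ValueError(f"tracks span several chromosomes: {sorted(chroms)}")

    n_panels = len(tracks) + (1 if dprime is not None else 0)
    fig, axes = plt.subplots(n_panels, 1, figsize=(9, 2.2 * n_panels), sharex=False)
    axes = np.atleast_1d(axes)
    for ax, t in zip(axes, tracks):
        ok = t.p is not None and np.isfinite(t.p).any()
        if ok:
            ax.scatter(t.pos / 1e6, -np.log10(t.p), s=4, c="steelblue")
        for y, style in ((np.log10(20), ":"), (2.0, "--")):  # p = 0.05, 0.01
            ax.axhline(y, color="red", linestyle=style, linewidth=0.8)
        if hotspots:
            for h in hotspots:
                ax.axvline(h / 1e6, color="red", linestyle=":", linewidth=0.5)
        ax.set_ylabel(f"{t.test}\n-log10 p")
    if genes:
        for name, start, end in genes:
            axes[len(tracks) - 1].axvspan(start / 1e6, end / 1e6, color="grey", alpha=0.2)
    if dprime is not None:
        ax = axes[-1]
        ax.imshow(dprime, cmap="YlOrRd", vmin=0, vmax=1, interpolation="nearest")
        ax.set_ylabel("|D'|")
    axes[min(len(tracks), len(axes)) - 1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig_path = out_prefix.with_suffix(".png")
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)

    rows = []
    for lst in clusters:
        for c in lst:
            rows.append((c.test, c.chrom, c.start, c.end, c.span, len(c.members), c.min_p))
    table = pd.DataFrame(
        rows, columns=["test", "chrom", "start", "end", "span_bp", "n_loci", "min_p"]
    ).sort_values(["chrom", "start", "test"], kind="stable")
    tsv_path = out_prefix.parent / (out_prefix.name + "_clusters.tsv")
    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")

    bed_path = out_prefix.parent / (out_prefix.name + "_candidates.bed")
    with open(bed_path, "w") as fh:
        if len([lst for lst in clusters if lst]) >= 2:
            for cand in intersect_clusters(clusters):
                fh.write(
                    f"{cand.chrom}\t{cand.start - 1}\t{cand.end}\t{'+'.join(cand.tests)}\t{cand.min_p:.3g}\n"
                )
    return fig_path, tsv_path, bed_path
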