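"""Cleaning QC: per-step statistics, k-mer overrepresentation, primer-match
and poly-A histograms, error-type tallies, and TSV/plot rendering.

The report mirrors the eight summary panels a protocol developer needs to
judge a run: (A) reads/bases/min/max length per step, (B) length
distribution per step, (C) quality-score distribution per step, (D) top
k-mers of the cleaned sequences, (E) primer-match histogram, (F) good/bad
reads by primer combination, (G) primer hits per base position, and (H)
lengths of trimmed poly-A tails / poly-T heads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .types import ACTIVE, Read


@dataclass
class StepStats:
    step: str
    n_reads: int = 0
    n_bases: int = 0
    min_len: int = 0
    max_len: int = 0
    len_hist: Counter = field(default_factory=Counter)
    qual_hist: Counter = field(default_factory=Counter)


def collect_step(reads: Iterable[Read], step_name: str) -> StepStats:
    """Statistics of the current clean intervals of active reads."""
    lens: Counter = Counter()
    quals: Counter = Counter()
    n = 0
    for read in reads:
        if read.status != ACTIVE:
            continue
        n += 1
        lens[read.clean.length] += 1
        cq = read.clean_qual
        if cq:
            quals.update(cq)
    n_bases = sum(length * count for length, count in lens.items())
    return StepStats(
        step=step_name,
        n_reads=n,
        n_bases=n_bases,
        min_len=min(lens) if lens else 0,
        max_len=max(lens) if lens else 0,
        len_hist=lens,
        qual_hist=quals,
    )


def top_kmers(reads: Iterable[Read], k: int = 6, top_n: int = 30) -> list[tuple[str, float]]:
    """Most frequent overlapping k-mers of the cleaned subsequences, as
    (k-mer, percent of all k-mers), ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for read in reads:
        seq = read.clean_seq if read.status == ACTIVE else None
        if not seq or len(seq) < k:
            continue
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    total = sum(counts.values())
    if total == 0:
        return []
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return [(kmer, 100.0 * c / total) for kmer, c in ranked]


@dataclass
class CleaningReport:
    steps: list[StepStats] = field(default_factory=list)
    kmer_top: list[tuple[str, float]] = field(default_factory=list)
    primer_match_hist: Counter = field(default_factory=Counter)  # (name, orientation) -> n
    combo_table: Counter = field(default_factory=Counter)        # taxonomy / combination -> n
    pos_hist: Counter = field(default_factory=Counter)           # position -> primer hits
    polya_hist: Counter = field(default_factory=Counter)         # trimmed tail length -> n
    polyt_hist: Counter = field(default_factory=Counter)
    discard_reasons: Counter = field(default_factory=Counter)

    def add_step(self, stats: StepStats) -> None:
        self.steps.append(stats)


_PANELS = "ABCDEFGH"


def render_report(report: CleaningReport, out_dir: str, plots: bool = False) -> dict[str, str]:
    """Write one TSV per panel (A-H) plus the discard-reason tally; return
    the paths.  ``plots=True`` additionally writes a PNG per panel."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    frames: dict[str, pd.DataFrame] = {}
    frames["A"] = pd.DataFrame(
        [
            {
                "step": s.step,
                "n_reads": s.n_reads,
                "n_bases": s.n_bases,
                "min_len": s.min_len,
                "max_len": s.max_len,
            }
            for s in report.steps
        ],
        columns=["step", "n_reads", "n_bases", "min_len", "max_len"],
    )
    frames["B"] = pd.DataFrame(
        [
            {"step": s.step, "length": length, "count": c}
            for s in report.steps
            for length, c in sorted(s.len_hist.items())
        ],
        columns=["step", "length", "count"],
    )
    frames["C"] = pd.DataFrame(
        [
            {"step": s.step, "quality": q, "count": c}
            for s in report.steps
            for q, c in sorted(s.qual_hist.items())
        ],
        columns=["step", "quality", "count"],
    )
    frames["D"] = pd.DataFrame(report.kmer_top, columns=["kmer", "percent"])
    frames["E"] = pd.DataFrame(
        [
            {"primer": name, "orientation": ori, "count": c}
            for (name, ori), c in sorted(report.primer_match_hist.items())
        ],
        columns=["primer", "orientation", "count"],
    )
    frames["F"] = pd.DataFrame(
        [{"combination": k, "count": c} for k, c in sorted(report.combo_table.items())],
        columns=["combination", "count"],
    )
    frames["G"] = pd.DataFrame(
        [{"position": p, "count": c} for p, c in sorted(report.pos_hist.items())],
        columns=["position", "count"],
    )
    frames["H"] = pd.DataFrame(
        [{"side": "polyA", "length": ln, "count": c} for ln, c in sorted(report.polya_hist.items())]
        + [
            {"side": "polyT", "length": ln, "count": c}
            for ln, c in sorted(report.polyt_hist.items())
        ],
        columns=["side", "length", "count"],
    )

    for panel in _PANELS:
        path = os.path.join(out_dir, f"panel_{panel}.tsv")
        frames[panel].to_csv(path, sep="\t", index=False)
        paths[panel] = path
    disc = pd.DataFrame(
        [{"reason": r, "count": c} for r, c in sorted(report.discard_reasons.items())],
        columns=["reason", "count"],
    )
    paths["discards"] = f"{out_dir}/discard_reasons.tsv"
    disc.to_csv(paths["discards"], sep="\t", index=False)

    if plots:
        paths.update(_render_plots(frames, out_dir))
    return paths


def _render_plots(frames: dict[str, pd.DataFrame], out_dir: str) -> dict[str, str]:
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, str] = {}
    for panel, df in frames.items():
        if df.empty:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        if panel == "A":
            ax.bar(df["step"], df["n_reads"])
            ax.set_ylabel("reads")
        elif panel in ("B", "C"):
            xcol = "length" if panel == "B" else "quality"
            for step, grp in df.groupby("step"):
                ax.plot(grp[xcol], grp["count"], label=step)
            ax.legend(fontsize=6)
            ax.set_xlabel(xcol)
        elif panel == "D":
            ax.bar(range(len(df)), df["percent"])
            ax.set_xticks(range(len(df)))
            ax.set_xticklabels(df["kmer"], rotation=90, fontsize=5)
            ax.set_ylabel("% of k-mers")
        elif panel == "E":
            labels = df["primer"] + ":" + df["orientation"]
            ax.bar(labels, df["count"])
            ax.tick_params(axis="x", rotation=45, labelsize=6)
        elif panel == "F":
            ax.bar(df["combination"], df["count"])
            ax.tick_params(axis="x", rotation=45, labelsize=6)
        elif panel == "G":
            ax.plot(df["position"], df["count"])
            ax.set_xlabel("position")
        elif panel == "H":
            for side, grp in df.groupby("side"):
                ax.plot(grp["length"], grp["count"], label=side)
            ax.legend()
            ax.set_xlabel("trimmed length")
        ax.set_title(f"panel {panel}")
        fig.tight_layout()
        path = os.path.join(out_dir, f"panel_{panel}.png")
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths[f"{panel}_png"] = path
    return paths
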