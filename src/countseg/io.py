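"""Reading count series and writing segmentation results.

Input formats: plain text (one non-negative integer per line) and
4-column bedGraph (chrom, start, end, value; 0-based half-open, one
chromosome per run, gaps filled with zero coverage — bedGraph intervals
arrive natively plateau-compressed, interval length = weight).

Output: a BED track of segments (0-based half-open), a TSV table
(1-based inclusive coordinates) and a JSON report with the full per-K
cost/criterion tables for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["CountInput", "read_counts", "write_segments"]


@dataclass(frozen=True)
class CountInput:
    """A dense count series plus optional genomic anchoring."""

    counts: np.ndarray
    chrom: str | None = None
    origin: int = 0  # 0-based genomic position of counts[0]

    @property
    def n(self) -> int:
        return len(self.counts)


def read_counts(path, fmt: str = "txt", chrom: str | None = None) -> CountInput:
    """Read a count series from ``path``.

    ``fmt="txt"``: one non-negative integer per line.  ``fmt="bedgraph"``:
    standard 4-column text; a single chromosome per run (pass ``chrom`` to
    pick one out of a multi-chromosome file); gaps between intervals are
    filled with zeros; the series starts at the first covered position.
    """
    if fmt == "txt":
        counts = np.loadtxt(path, dtype=np.int64, ndmin=1)
        if counts.ndim != 1:
            raise ValueError("expected a single column of integers")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        return CountInput(counts)
    if fmt != "bedgraph":
        raise ValueError(f"unknown input format {fmt!r}")

    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    chroms = df["chrom"].unique()
    if chrom is None:
        if len(chroms) > 1:
            raise ValueError(
                f"bedGraph covers {len(chroms)} chromosomes ({', '.join(chroms[:5])}...); "
                "choose one with chrom="
            )
        chrom = chroms[0]
    sub = df[df["chrom"] == chrom].sort_values("start")
    if sub.empty:
        raise ValueError(f"no intervals for chromosome {chrom!r}")
    vals = sub["value"].to_numpy()
    if np.any(vals < 0) or np.any(vals != np.round(vals)):
        raise ValueError("bedGraph values must be non-negative integers for count models")
    origin = int(sub["start"].iloc[0])
    n = int(sub["end"].iloc[-1]) - origin
    counts = np.zeros(n, dtype=np.int64)
    for s, e, v in zip(sub["start"], sub["end"], vals):
        if e <= s:
            raise ValueError("bedGraph interval with end <= start")
        counts[s - origin : e - origin] = int(v)
    return CountInput(counts, chrom=chrom, origin=origin)


def write_segments(results, out_prefix: str, k: int | None = None,
                   criterion: str = "oracle", chrom: str | None = None,
                   origin: int = 0, config: dict | None = None) -> dict:
    """Write BED + TSV + JSON for a fitted :class:`SegmentationResults`.

    Returns the JSON report as a dict.  ``k`` defaults to the criterion's
    selected number of segments.
    """
    tab = results.select(criterion)
    k = tab.K_hat if k is None else k
    seg_df = results.segment_table(k)
    chrom = chrom or "series"

    bed_path = f"{out_prefix}.bed"
    tsv_path = f"{out_prefix}.segments.tsv"
    json_path = f"{out_prefix}.report.json"

    with open(bed_path, "w") as fh:
        fh.write(f'track name="countseg" description="countseg v{__version__} '
                 f'{results.segmentation.model.family} K={k}"\n')
        for row in seg_df.itertuples():
            # BED: 0-based half-open; score = fitted mean clipped to [0, 1000]
            score = int(min(1000, max(0, round(row.mean))))
            fh.write(f"{chrom}\t{origin + row.start - 1}\t{origin + row.end}\t"
                     f"seg{row.segment}\t{score}\t.\n")

    with open(tsv_path, "w") as fh:
        fh.write(f"# countseg v{__version__}; coordinates 1-based inclusive\n")
        seg_df.to_csv(fh, sep="\t", index=False)

    report = {
        "version": __version__,
        "config": config or {},
        "n": int(results.nobs),
        "effective_points": int(results.segmentation.m),
        "family": results.segmentation.model.family,
        "phi": float(results.phi) if results.segmentation.model.family == "nbinom" else None,
        "phi_estimated": results.phi_estimate is not None,
        "kmax": int(results.kmax),
        "criterion": criterion,
        "beta": tab.beta,
        "K_hat": int(tab.K_hat),
        "K_written": int(k),
        "costs": [float(c) for c in tab.cost],
        "criterion_values": [float(v) for v in tab.values],
        "breakpoints": {
            str(kk): [int(b) for b in results.breakpoints(kk)]
            for kk in range(1, results.kmax + 1)
        },
    }
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=1)
    return report
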