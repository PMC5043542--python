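"""Window statistics on pooled-sequencing allele counts.

Pooled heterozygosity in a window is H_p = 2*Sum(n_MAJ)*Sum(n_MIN) /
(Sum(n_MAJ) + Sum(n_MIN))^2, where n_MAJ/n_MIN are per-site read counts of the
major and minor allele and the sums run over all sites in a 50-kb
non-overlapping window.  ZH_p standardizes H_p across all defined windows
(genome-wide by default).  High ZH_p marks regions of local population
structure such as inversion breakpoints; low ZH_p marks fixation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MACSpectrum:
    """Histogram of minor-allele read-count frequencies in a region."""

    bin_edges: np.ndarray
    counts: np.ndarray
    region: str = ""

    def local_maxima(self, min_ratio: float = 1.5) -> list:
        """Bins exceeding both neighbors and ``min_ratio`` x the median bin count.

        Returns (bin_low, bin_high) tuples.
        """
        c = self.counts.astype(float)
        med = np.median(c)
        floor = min_ratio * med if med > 0 else min_ratio
        peaks = []
        for i in range(len(c)):
            left = c[i - 1] if i > 0 else -np.inf
            right = c[i + 1] if i < len(c) - 1 else -np.inf
            if c[i] > left and c[i] > right and c[i] >= floor:
                peaks.append((float(self.bin_edges[i]), float(self.bin_edges[i + 1])))
        return peaks


def _window_index(pos: np.ndarray, window_bp: int) -> np.ndarray:
    # windows anchored at position 1: [1, w], [w+1, 2w], ...
    return (pos - 1) // window_bp


def pooled_heterozygosity_windows(counts, window_bp: int = 50_000) -> pd.DataFrame:
    """Per-window pooled heterozygosity on a non-overlapping grid.

    Windows with zero total reads (or no sites) carry ``NaN`` H_p, not 0.
    The trailing partial window of each chromosome is retained and flagged.
    """
    sites = counts.sites
    out = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("pooled counts must be position-sorted within chromosome")
        win = _window_index(pos, window_bp)
        last = int(win.max()) if len(win) else 0
        grouped = pd.DataFrame(
            {"win": win, "n_maj": sub["n_maj"].to_numpy(), "n_min": sub["n_min"].to_numpy()}
        ).groupby("win")
        agg = grouped.agg(maj=("n_maj", "sum"), mino=("n_min", "sum"), n_sites=("n_maj", "size"))
        for w in range(last + 1):
            start, end = w * window_bp + 1, (w + 1) * window_bp
            if w in agg.index:
                maj, mino, n_sites = agg.loc[w, ["maj", "mino", "n_sites"]]
                tot = maj + mino
                hp = 2.0 * maj * mino / tot**2 if tot > 0 else np.nan
            else:
                hp, n_sites = np.nan, 0
            out.append((chrom, start, end, hp, int(n_sites), w == last))
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "hp", "n_sites", "partial"]
    )


def zscore_windows(windows: pd.DataFrame, per_chromosome: bool = False) -> pd.DataFrame:
    """Add the ZH_p column: (H_p - mean) / sd over all defined windows.

    The sample (n-1) standard deviation is used; a zero-variance set of
    defined H_p values is an error.
    """

    def _z(hp: pd.Series) -> pd.Series:
        ok = hp.dropna()
        if len(ok) < 2:
            raise ValueError("need >= 2 defined windows for Z-scores")
        sd = ok.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance in H_p; Z-scores undefined")
        return (hp - ok.mean()) / sd

    windows = windows.copy()
    if per_chromosome:
        windows["zhp"] = windows.groupby("chrom")["hp"].transform(_z)
    else:
        windows["zhp"] = _z(windows["hp"])
    return windows


def diversity_windows(counts, window_bp: int = 50_000) -> pd.DataFrame:
    """SNPs per site per window; a site is a SNP iff both allele counts > 0."""
    sites = counts.sites
    seg = (sites["n_maj"] > 0) & (sites["n_min"] > 0)
    out = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        win = _window_index(sub["pos"].to_numpy(), window_bp)
        seg_sub = seg.loc[sub.index].to_numpy()
        last = int(win.max()) if len(win) else 0
        n_seg = np.bincount(win[seg_sub], minlength=last + 1)
        for w in range(last + 1):
            out.append(
                (chrom, w * window_bp + 1, (w + 1) * window_bp, n_seg[w] / window_bp, int(n_seg[w]))
            )
    return pd.DataFrame(out, columns=["chrom", "start", "end", "snps_per_site", "n_segregating"])


def mac_spectrum(counts, region=None, bin_width: float = 0.02, label: str = "") -> MACSpectrum:
    """Minor-allele read-fraction spectrum of the SNPs in a region.

    ``region`` is (chrom, start, end) (1-based inclusive) or ``None`` for all
    sites.  Fixed sites (either allele count zero) are excluded, so a fully
    fixed region gives an empty spectrum.
    """
    sites = counts.sites
    if region is not None:
        chrom, start, end = region
        sites = sites[
            (sites["chrom"] == chrom) & (sites["pos"] >= start) & (sites["pos"] <= end)
        ]
    if len(sites) == 0 and region is not None:
        raise ValueError("region contains no sites")
    seg = sites[(sites["n_maj"] > 0) & (sites["n_min"] > 0)]
    depth = seg["n_maj"] + seg["n_min"]
    mac = (seg["n_min"] / depth).to_numpy()
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    hist, _ = np.histogram(mac, bins=edges)
    return MACSpectrum(bin_edges=edges, counts=hist, region=label)
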