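"""Positional conservation: per-column index, element binning, inside/outside test.

The conservation index is an entropy measure over alignment columns: for
column c with gap-excluded amino-acid frequencies f_a(c), the raw score is
-H(c) = sum_a f_a(c) ln f_a(c) (so higher = more conserved), z-normalized
across scored columns so the profile is centered (mean 0, sd 1).  Columns
with more than 50% gaps are left unscored.  Sequence weighting and window
smoothing are available but off by default.

Element binning maps a per-residue conservation trace of length L onto a
fixed number of bins B by evaluating the piecewise-constant trace at each
bin center (i + 0.5) * L / B -- this handles both partitioning (L > B) and
stretching (L < B), so elements of different lengths become comparable and
can be averaged across many family representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .rlm_search import RLMMatch

__all__ = [
    "ConservationProfile",
    "BinnedProfile",
    "ConstantProfileError",
    "read_msa",
    "conservation_index",
    "map_to_reference",
    "bin_element",
    "bin_profile",
    "default_bin_counts",
    "aggregate_bins",
    "ks_compare",
    "inside_outside_test",
]

GAP_CHARS = frozenset("-.")

#: order of binned regions in a BinnedProfile
BIN_REGIONS = ("I", "II", "III", "IV", "V")


class ConstantProfileError(ValueError):
    """All scored columns have identical index values; z-score undefined."""


@dataclass
class ConservationProfile:
    """Per-column conservation; NaN marks unscored (gap-heavy) columns."""

    values: np.ndarray  # z-normalized, length = alignment columns
    raw: np.ndarray     # -entropy before normalization

    def scored(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]


@dataclass
class BinnedProfile:
    """Per-element bin means (optionally with SE after aggregation)."""

    bins: dict[str, np.ndarray]
    se: dict[str, np.ndarray] = field(default_factory=dict)
    n: int = 1

    def layout(self) -> tuple[tuple[str, int], ...]:
        return tuple((k, len(v)) for k, v in self.bins.items())


def read_msa(path) -> list[str]:
    """Read an aligned FASTA file into a list of equal-length row strings."""
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "fasta")
    return [str(rec.seq).upper() for rec in aln]


def _rows(msa) -> list[str]:
    rows = [str(getattr(r, "seq", r)).upper() for r in msa]
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    return rows


def conservation_index(
    msa,
    *,
    max_gap_fraction: float = 0.5,
    weights: np.ndarray | None = None,
    smooth_window: int = 0,
) -> ConservationProfile:
    """Centered entropy-based conservation index per alignment column.

    ``weights`` optionally gives one weight per sequence (normalized
    internally); ``smooth_window`` > 1 applies a running mean over scored
    columns before normalization.
    """
    rows = _rows(msa)
    n_seq, L = len(rows), len(rows[0])
    w = np.ones(n_seq) if weights is None else np.asarray(weights, float)
    if w.shape != (n_seq,) or (w <= 0).any():
        raise ValueError("weights must be positive, one per sequence")

    raw = np.full(L, np.nan)
    for c in range(L):
        col = [r[c] for r in rows]
        keep = [i for i, ch in enumerate(col) if ch not in GAP_CHARS]
        if len(keep) < (1.0 - max_gap_fraction) * n_seq or len(keep) < 2:
            continue
        freq: dict[str, float] = {}
        for i in keep:
            freq[col[i]] = freq.get(col[i], 0.0) + w[i]
        f = np.array(list(freq.values()))
        f = f / f.sum()
        raw[c] = float((f * np.log(f)).sum())  # = -entropy
    scored = ~np.isnan(raw)
    if not scored.any():
        raise ValueError("all columns are gap-dominated; nothing to score")

    vals = raw.copy()
    if smooth_window > 1:
        idx = np.flatnonzero(scored)
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.convolve(vals[idx], kernel, mode="same")
        vals[idx] = sm
    mu = np.nanmean(vals)
    sd = np.nanstd(vals)
    if sd < 1e-12:
        raise ConstantProfileError("constant conservation profile (sd = 0)")
    vals = (vals - mu) / sd
    return ConservationProfile(values=vals, raw=raw)


def map_to_reference(
    profile: ConservationProfile, msa, ref_index: int = 0, start_number: int = 1
) -> dict[int, float]:
    """Map column values onto the ungapped residue numbering of one row."""
    rows = _rows(msa)
    ref = rows[ref_index]
    out: dict[int, float] = {}
    num = start_number
    for c, ch in enumerate(ref):
        if ch in GAP_CHARS:
            continue
        out[num] = float(profile.values[c])
        num += 1
    return out


def bin_element(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Evaluate a length-L piecewise-constant trace at ``n_bins`` bin centers.

    Bin i takes the value at position (i + 0.5) * L / B, i.e. the residue
    with index floor of that position.  Exact identity when L == B.
    """
    values = np.asarray(values, float)
    L = len(values)
    if L == 0:
        raise ValueError("empty element; cannot bin")
    if n_bins < 1:
        raise ValueError("bin count must be >= 1")
    centers = (np.arange(n_bins) + 0.5) * L / n_bins
    idx = np.minimum(np.floor(centers).astype(int), L - 1)
    return values[idx]


def bin_profile(
    per_residue: dict[int, float], match: RLMMatch, bins: dict[str, int]
) -> BinnedProfile:
    """Bin a residue-mapped conservation trace element-by-element.

    ``per_residue`` maps residue number -> conservation value (e.g. from
    :func:`map_to_reference`); ``bins`` gives the bin count per element name.
    Elements absent from the match (loop-IV) are skipped.
    """
    out: dict[str, np.ndarray] = {}
    for name in BIN_REGIONS:
        if name not in bins or match.elements.get(name) is None:
            continue
        residues = match.element_residues(name)
        vals = [per_residue[r.number] for r in residues if r.number in per_residue]
        if not vals:
            raise ValueError(f"profile does not cover element {name}")
        out[name] = bin_element(np.array(vals), bins[name])
    return BinnedProfile(bins=out)


def default_bin_counts(matches: list[RLMMatch]) -> dict[str, int]:
    """Per-element bin counts = rounded mean element length over the input set."""
    counts: dict[str, int] = {}
    for name in BIN_REGIONS:
        lengths = [
            len(m.element_residues(name))
            for m in matches
            if m.elements.get(name) is not None
        ]
        if lengths:
            counts[name] = max(1, round(float(np.mean(lengths))))
    return counts


def aggregate_bins(profiles: list[BinnedProfile]) -> BinnedProfile:
    """Mean and standard error per bin over profiles with identical layout."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    layout = profiles[0].layout()
    if any(p.layout() != layout for p in profiles):
        raise ValueError("binned profiles have mismatched layouts")
    n = len(profiles)
    means: dict[str, np.ndarray] = {}
    ses: dict[str, np.ndarray] = {}
    for name, _ in layout:
        stack = np.stack([p.bins[name] for p in profiles])
        means[name] = stack.mean(axis=0)
        if n > 1:
            ses[name] = stack.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            ses[name] = np.zeros(stack.shape[1])
    return BinnedProfile(bins=means, se=ses, n=n)


def ks_compare(vals_in, vals_out) -> tuple[float, float, float, float]:
    """(mean_in, mean_out, KS D, asymptotic two-sided p) for two value sets.

    The p-value is the Kolmogorov-distribution tail Q(sqrt(nm/(n+m)) * D);
    exact small-sample p-values are out of scope.
    """
    vals_in = np.asarray(vals_in, float)
    vals_out = np.asarray(vals_out, float)
    if vals_in.size == 0 or vals_out.size == 0:
        raise ValueError("inside/outside partition is empty")
    d = float(stats.ks_2samp(vals_in, vals_out, method="asymp").statistic)
    n, m = vals_in.size, vals_out.size
    p = float(special.kolmogorov(d * np.sqrt(n * m / (n + m))))
    return float(vals_in.mean()), float(vals_out.mean()), d, p


def inside_outside_test(
    per_residue: dict[int, float], match: RLMMatch
) -> tuple[float, float, float, float]:
    """Compare conservation of motif residues against the rest of the domain.

    Partitions the residue-mapped values into RLM residues (elements I-V plus
    both loops) versus all remaining residues, and returns
    (mean_in, mean_out, KS D, asymptotic two-sided p).
    """
    inside_nums = {r.number for r in match.all_rlm_residues()}
    vals_in = [v for num, v in per_residue.items() if num in inside_nums]
    vals_out = [v for num, v in per_residue.items() if num not in inside_nums]
    return ks_compare(vals_in, vals_out)
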