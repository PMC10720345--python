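"""Potential-of-mean-force estimation and basin free-energy differences.

The PMF over a collective variable alpha is V(alpha) = -RT ln(P(alpha)/max P)
with P the normalized histogram of target-state samples; the max-probability
normalization puts the global minimum at exactly 0.  Basin free-energy
differences are computed from integrated basin probabilities (the Boltzmann
weights of the conformers), not from PMF minima, with uncertainties from
block averaging over the sample time series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model_systems import BasinPartition, ThermoState


@dataclass
class PMFResult:
    """Binned probabilities and the derived PMF (1D or 2D).

    ``p`` sums to 1 over unmasked bins; ``v`` is -RT ln(p / max p), >= 0 with
    minimum exactly 0; ``mask`` is True on empty bins (V undefined there,
    never +/-inf).
    """

    edges: tuple           # one edge array per dimension
    p: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    thermo: ThermoState

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)


def _histogram_pmf(counts, edges, thermo):
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples fell inside the binning range")
    p = counts / total
    mask = counts == 0
    if mask.sum() == mask.size - 1:
        warnings.warn("all samples fall in a single bin; PMF is 0 there and "
                      "masked elsewhere", stacklevel=3)
    v = np.zeros_like(p)
    pm = p.max()
    nz = ~mask
    v[nz] = -thermo.rt * np.log(p[nz] / pm)
    v[mask] = np.nan
    return PMFResult(edges=edges, p=p, v=v, mask=mask, thermo=thermo)


def pmf_1d(samples, bins, thermo: ThermoState, range=None) -> PMFResult:
    """1D PMF from samples of a collective variable.

    ``bins`` may be a count or explicit edges; ``range`` bounds the histogram
    (defaults to the data range).  For a periodic angle pass the full period,
    e.g. range=(-180, 180) for degrees.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1:
        raise ValueError("need at least one sample")
    if np.isscalar(bins) and int(bins) < 2:
        raise ValueError("need at least 2 bins")
    counts, edges = np.histogram(samples, bins=bins, range=range)
    return _histogram_pmf(counts.astype(float), (edges,), thermo)


def pmf_2d(samples_x, samples_y, bins, thermo: ThermoState, range=None) -> PMFResult:
    """2D PMF from paired samples; same normalization and masking as pmf_1d."""
    x = np.asarray(samples_x, dtype=float)
    y = np.asarray(samples_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples_x and samples_y must have equal length")
    if x.size < 1:
        raise ValueError("need at least one sample")
    counts, ex, ey = np.histogram2d(x, y, bins=bins, range=range)
    return _histogram_pmf(counts.astype(float), (ex, ey), thermo)


def basin_populations(samples, basins: BasinPartition, n_blocks: int = 10):
    """Basin occupancy fractions with block-averaged standard errors.

    Returns (p, se): arrays over basins.  Fractions are taken over *labelled*
    samples; the time series is split into ``n_blocks`` contiguous blocks and
    the SE of each fraction is std(block means)/sqrt(n_blocks).
    """
    samples = np.asarray(samples, dtype=float)
    labels = basins.classify(samples)
    nb = len(basins.intervals)
    blocks = np.array_split(labels, n_blocks)
    per_block = []
    for blk in blocks:
        lab = blk[blk >= 0]
        if lab.size:
            per_block.append(np.bincount(lab, minlength=nb) / lab.size)
    if not per_block:
        raise ValueError("no labelled samples in any block")
    per_block = np.array(per_block)
    lab_all = labels[labels >= 0]
    p = np.bincount(lab_all, minlength=nb) / lab_all.size
    se = per_block.std(axis=0, ddof=1) / math.sqrt(len(per_block)) \
        if len(per_block) > 1 else np.full(nb, np.nan)
    return p, se


def basin_delta_f(samples, basins: BasinPartition, thermo: ThermoState,
                  n_blocks: int = 10):
    """Pairwise basin free-energy differences dF_ab = -RT ln(p_b / p_a).

    Computed from integrated basin probabilities (sums over samples), not PMF
    minima.  Returns a dict {(label_a, label_b): (dF, se)} for a < b; the SE
    comes from block averaging of per-block dF estimates (blocks where either
    basin is empty are dropped).  Pairs involving an empty basin get dF = nan.
    """
    samples = np.asarray(samples, dtype=float)
    labels = basins.classify(samples)
    nb = len(basins.intervals)
    names = basins.labels
    lab_all = labels[labels >= 0]
    if lab_all.size == 0:
        raise ValueError("no labelled samples")
    counts = np.bincount(lab_all, minlength=nb)
    blocks = np.array_split(labels, n_blocks)
    out = {}
    for a in range(nb):
        for b in range(a + 1, nb):
            if counts[a] == 0 or counts[b] == 0:
                out[(names[a], names[b])] = (math.nan, math.nan)
                continue
            df = -thermo.rt * math.log(counts[b] / counts[a])
            per = []
            for blk in blocks:
                lab = blk[blk >= 0]
                ca = np.count_nonzero(lab == a)
                cb = np.count_nonzero(lab == b)
                if ca > 0 and cb > 0:
                    per.append(-thermo.rt * math.log(cb / ca))
            se = float(np.std(per, ddof=1) / math.sqrt(len(per))) if len(per) > 1 else math.nan
            out[(names[a], names[b])] = (float(df), se)
    return out
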