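"""ChIP-Rx spike-in normalisation, global mark level, and qPCR enrichment.

A ChIP-Rx experiment mixes a fixed proportion of exogenous (spike-in,
e.g. drosophila) chromatin into every sample before immunoprecipitation.
Because every sample receives the same exogenous amount, the exogenous read
yield calibrates IP efficiency and global mark abundance across samples:

* per-sample *scaling factors* equalise samples for downsampling, and
* the *global mark level*  (H_IP / D_IP) / (H_in / D_in)  is a depth-invariant
  estimate of genome-wide occupancy (H = target-genome reads, D = spike-in
  reads, IP vs input role).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SpikeInCounts:
    """Per-sample read tallies split by genome of origin and IP/input role."""

    h_ip: int
    d_ip: int
    h_in: int = 0
    d_in: int = 0

    def __post_init__(self) -> None:
        for name in ("h_ip", "d_ip", "h_in", "d_in"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def counts_from_fragments(frags: pd.DataFrame) -> dict[str, SpikeInCounts]:
    """Tally a fragment table into per-sample :class:`SpikeInCounts`."""
    out: dict[str, SpikeInCounts] = {}
    if not len(frags):
        return out
    grouped = frags.groupby(["sample", "genome", "role"]).size()
    for sample in frags["sample"].unique():
        def n(genome: str, role: str) -> int:
            return int(grouped.get((sample, genome, role), 0))

        out[sample] = SpikeInCounts(
            h_ip=n("target", "IP"),
            d_ip=n("spikein", "IP"),
            h_in=n("target", "input"),
            d_in=n("spikein", "input"),
        )
    return out


def initial_scaling_factors(
    counts: Mapping[str, SpikeInCounts],
    input_correct: bool = False,
    constant: float = 1e6,
) -> dict[str, float]:
    """Initial per-sample scaling factors from spike-in IP read counts.

    Without input correction the factor is ``constant / D_IP`` (reads-per-
    million style; the constant cancels after max-adjustment).  With
    ``input_correct`` the IP spike-in fraction is normalised by the input
    spike-in fraction:

        sf_i = constant * (H_IP_i / D_IP_i) * (H_in_i / D_in_i)

    which corrects for sample-to-sample differences in the spike-in
    proportion actually present in the input material.
    """
    if not counts:
        raise ValueError("no samples given")
    out: dict[str, float] = {}
    for sample, c in counts.items():
        if c.d_ip == 0:
            raise ValueError(f"sample {sample!r}: zero spike-in IP reads")
        if input_correct:
            if c.d_in == 0 or c.h_in == 0:
                raise ValueError(
                    f"sample {sample!r}: input correction needs H_in and D_in > 0"
                )
            out[sample] = constant * (c.h_ip / c.d_ip) * (c.h_in / c.d_in)
        else:
            out[sample] = constant / c.d_ip
    return out


def adjust_scaling_factors(initial_sf: Mapping[str, float]) -> pd.DataFrame:
    """Divide each factor by the group maximum so the largest becomes 1.

    Samples must already be grouped by ChIP antibody; the adjustment is
    within-group.  Returns a frame with columns (sample, initial_sf,
    adjusted_sf); adjusted factors lie in (0, 1] with max exactly 1.
    """
    if not initial_sf:
        raise ValueError("empty scaling-factor group")
    if any(v <= 0 for v in initial_sf.values()):
        raise ValueError("initial scaling factors must be positive")
    sf_max = max(initial_sf.values())
    return pd.DataFrame(
        {
            "sample": list(initial_sf),
            "initial_sf": [initial_sf[s] for s in initial_sf],
            "adjusted_sf": [initial_sf[s] / sf_max for s in initial_sf],
        }
    )


def downsample_fragments(
    frags: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Keep each fragment independently with probability ``fraction``.

    Bernoulli thinning under a seeded generator: the same seed and input
    reproduce the output exactly.  ``fraction`` must lie in (0, 1];
    fraction 1 returns the input unchanged.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0 or not len(frags):
        return frags.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(frags)) < fraction
    return frags.loc[keep].reset_index(drop=True)


def global_mark_level(counts: SpikeInCounts) -> float:
    """Depth-invariant global occupancy:  (H_IP / D_IP) / (H_in / D_in)."""
    if counts.d_ip == 0 or counts.d_in == 0 or counts.h_in == 0:
        raise ValueError("global mark level needs D_IP, D_in and H_in > 0")
    return (counts.h_ip / counts.d_ip) / (counts.h_in / counts.d_in)


def read_spikein_counts(path: str | Path) -> dict[str, SpikeInCounts]:
    """Read a TSV of (sample, H_IP, D_IP, H_in, D_in)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return {
        r.sample: SpikeInCounts(int(r.H_IP), int(r.D_IP), int(r.H_in), int(r.D_in))
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# ChIP-qPCR


def qpcr_percent_input(
    ct_ip: float, ct_input: float, input_fraction: float = 0.01
) -> float:
    """Percent-of-input enrichment from IP and diluted-input Ct values.

    The input aliquot is a fraction ``f`` of the IP material, so its Ct is
    first adjusted by log2(1/f) cycles; enrichment is then
    ``100 * 2^(adjusted input Ct - IP Ct)``.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input fraction must be in (0, 1]")
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    adjusted_input = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - ct_ip)


def normalise_to_h3(mark_percent: float, h3_percent: float) -> float:
    """Normalise a mark's percent-input enrichment by total-H3 enrichment."""
    if h3_percent <= 0:
        raise ValueError("H3-total enrichment must be positive")
    return mark_percent / h3_percent


def qpcr_table(ct: pd.DataFrame, input_fraction: float = 0.01) -> pd.DataFrame:
    """Percent-input and H3-normalised enrichment for a Ct table.

    Expects columns (region, sample, antibody, ct, ct_input); antibody is
    the mark name, ``H3total`` for the normaliser, or ``none`` for the
    no-antibody control.  Raises if any (region, sample) lacks an H3total row.
    """
    rows = []
    for (region, sample), grp in ct.groupby(["region", "sample"], sort=True):
        h3 = grp[grp["antibody"] == "H3total"]
        if h3.empty:
            raise ValueError(f"missing H3total row for region={region!r} sample={sample!r}")
        f = input_fraction
        if "input_fraction" in grp.columns:
            f = float(grp["input_fraction"].iloc[0])
        h3_pct = qpcr_percent_input(
            float(h3["ct"].iloc[0]), float(h3["ct_input"].iloc[0]), f
        )
        for r in grp.itertuples():
            pct = qpcr_percent_input(float(r.ct), float(r.ct_input), f)
            rows.append(
                {
                    "region": region,
                    "sample": sample,
                    "antibody": r.antibody,
                    "percent_input": pct,
                    "normalised": pct / h3_pct,
                }
            )
    return pd.DataFrame(rows)
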