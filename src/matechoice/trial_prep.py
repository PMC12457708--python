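"""Make the four mating contexts comparable on a common binary scale.

Competitive vials identify one winner among four males, so a randomly
sampled male succeeds with probability 1/4.  Noncompetitive latency trials
are therefore binarized at the 25th percentile of latency within each
block x female-status group (censored trials counting as slower than any
observed latency); groups whose raw mated fraction is already below the
target quantile keep their raw mated flags.  Competitive vials are reduced
to one independent binary row each by sampling one male per vial, and that
sampling is repeated R times to propagate its uncertainty into the model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "binarize_latency",
    "resample_competitive",
    "build_resample_sets",
    "mated_competitive",
    "combine_contexts",
]

_STATUSES = ("virgin", "nonvirgin")


def _censored_quantile(lat: np.ndarray, q: float) -> float:
    """Linear-interpolation empirical quantile tolerating +inf entries
    (any interpolation weight on a censored value yields +inf)."""
    xs = np.sort(lat)
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    if np.isinf(xs[hi]):
        return xs[lo] if h == lo else np.inf
    return float(xs[lo] + (h - lo) * (xs[hi] - xs[lo]))


def binarize_latency(trials: pd.DataFrame, quantile: float = 0.25) -> pd.DataFrame:
    """Score noncompetitive trials as success/failure at a latency quantile.

    Within each block x status group, success = mated and latency at or
    below the group's empirical ``quantile`` of latency, computed over all
    trials in the group with censored latencies treated as +inf.  If the
    group's raw mated fraction is below ``quantile`` the raw mated flags
    are returned unchanged (binarizing further would only discard signal).

    Returns a binary outcome table with one row per trial (columns:
    block, context, male_strain, female_strain, success, source_vial).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    bad = set(trials["status"]) - set(_STATUSES)
    if bad:
        raise ValueError(f"unknown status label(s): {sorted(bad)}")
    out = []
    for (block, status), grp in trials.groupby(["block", "status"], sort=False):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empty
            raise ValueError(f"empty group: block={block!r}, status={status!r}")
        mated = grp["mated"].to_numpy(dtype=bool)
        frac = mated.mean()
        if frac < quantile:
            success = mated
        else:
            lat = grp["latency_min"].to_numpy(dtype=float).copy()
            lat[~mated] = np.inf
            thresh = _censored_quantile(lat, quantile)
            success = mated & (lat <= thresh)
        g = pd.DataFrame(
            {
                "block": grp["block"].to_numpy(),
                "context": grp["context"].to_numpy(),
                "male_strain": grp["male_strain"].to_numpy(),
                "female_strain": grp["female_strain"].to_numpy(),
                "color": "",
                "success": success.astype(int),
                "source_vial": grp["vial"].to_numpy(),
            }
        )
        out.append(g)
    return pd.concat(out, ignore_index=True)


def mated_competitive(vials: pd.DataFrame) -> pd.DataFrame:
    """Drop competitive vials with no mating or no identified winner."""
    keep = vials["mated"].astype(bool) & (vials["winner_strain"].astype(str) != "")
    return vials.loc[keep].reset_index(drop=True)


def resample_competitive(vials: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Sample one male per mated vial; success = sampled male won.

    Every input vial must have an identified winner (non-mating vials and
    unidentified winners are excluded upstream, as they carry no usable
    outcome).  The sampled male's strain and color are recorded so the
    model can include the dye-color fixed effect.
    """
    winners = vials["winner_strain"].astype(str)
    if (~vials["mated"].astype(bool)).any() or (winners == "").any():
        raise ValueError(
            "competitive vials without an identified winner; "
            "filter with mated_competitive() first"
        )
    rng = np.random.default_rng(seed)
    colors = ("black", "blue", "green", "red")
    pick = rng.integers(0, 4, size=len(vials))
    male_cols = [vials[f"male_{c}"].to_numpy() for c in colors]
    sampled_strain = np.choose(pick, male_cols)
    sampled_color = np.asarray(colors)[pick]
    return pd.DataFrame(
        {
            "block": vials["block"].to_numpy(),
            "context": vials["context"].to_numpy(),
            "male_strain": sampled_strain,
            "female_strain": "",
            "color": sampled_color,
            "success": (sampled_strain == winners.to_numpy()).astype(int),
            "source_vial": vials["vial"].to_numpy(),
        }
    )


def build_resample_sets(
    vials: pd.DataFrame, n_resamples: int = 100, seed: int = 0
) -> list[pd.DataFrame]:
    """R independent one-male-per-vial resamples (sub-seed = seed + index)."""
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    return [resample_competitive(vials, seed + i) for i in range(n_resamples)]


def combine_contexts(
    noncomp_binary: pd.DataFrame, comp_binary: pd.DataFrame
) -> pd.DataFrame:
    """Stack noncompetitive and competitive binary rows into one table."""
    return pd.concat([noncomp_binary, comp_binary], ignore_index=True)
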