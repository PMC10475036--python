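"""Similarity of subject contrast vectors to a binary network mask.

The frontoparietal-network analysis scores each subject's contrast vector
(parcel- or voxel-wise amplitudes on a common grid) by its Pearson
correlation with the binary network indicator, Fisher-z transformed.  Up
to a monotone transform this equals the standardized in-mask vs out-of-mask
mean difference (the point-biserial identity), so larger z means stronger
relative engagement of the network.  Group comparisons and correlations
with behavioural learning biases then run on the z values.

The default grid is an abstract parcel vector; volumetric masks can be
flattened to the same representation upstream (e.g. via nibabel) without
changing any operation here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference_stats as infs

__all__ = [
    "NetworkMask",
    "mask_similarity",
    "group_network_test",
    "make_synthetic_mask",
    "synthetic_contrast_map",
]


@dataclass(frozen=True)
class NetworkMask:
    """Binary indicator over the parcel grid; needs both classes present."""

    indicator: np.ndarray
    name: str = "frontoparietal"

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")
        if ind.min() == ind.max():
            raise ValueError("mask needs at least one 1 and one 0")
        object.__setattr__(self, "indicator", ind.astype(float))


def mask_similarity(values, mask: NetworkMask) -> float:
    """Fisher-z Pearson similarity of a contrast vector with the mask.

    Raises for a constant map and for |r| = 1 (infinite z).
    """
    v = np.asarray(values, dtype=float)
    if v.shape != mask.indicator.shape:
        raise ValueError("contrast vector and mask length mismatch")
    if np.ptp(v) == 0:
        raise infs.DegenerateInputError("constant contrast map")
    r = float(np.corrcoef(v, mask.indicator)[0, 1])
    return infs.fisher_z(r)  # raises on |r| >= 1


def group_network_test(similarity: pd.DataFrame,
                       group_a: str = "HC", group_b: str = "SAD") -> dict:
    """Group comparison of network-similarity z plus behavioural correlations.

    ``similarity`` needs columns ``z`` and ``group``; optional columns
    ``bias`` (social-influence or learning bias) and ``beta_pos`` are each
    Spearman-correlated with z.  The group test is Welch's t (group_a
    minus group_b).
    """
    za = similarity.loc[similarity["group"] == group_a, "z"].to_numpy()
    zb = similarity.loc[similarity["group"] == group_b, "z"].to_numpy()
    if len(za) < 2 or len(zb) < 2:
        raise ValueError("need >= 2 subjects per group")
    out = {"group_test": infs.welch_t(za, zb)}
    for col in ("bias", "beta_pos"):
        if col in similarity:
            out[f"spearman_{col}"] = infs.spearman(
                similarity["z"].to_numpy(), similarity[col].to_numpy())
    return out


def make_synthetic_mask(n_parcels: int = 1000, frac_in: float = 0.2,
                        rng=None, name: str = "frontoparietal") -> NetworkMask:
    """Random binary mask with ``frac_in`` of parcels in-network."""
    rng = np.random.default_rng(rng)
    n_in = max(1, min(n_parcels - 1, int(round(frac_in * n_parcels))))
    ind = np.zeros(n_parcels)
    ind[rng.choice(n_parcels, size=n_in, replace=False)] = 1.0
    return NetworkMask(indicator=ind, name=name)


def synthetic_contrast_map(mask: NetworkMask, in_mask_signal: float,
                           noise_sd: float = 1.0, rng=None) -> np.ndarray:
    """Parcel vector: unit Gaussian noise plus a mean shift inside the mask."""
    rng = np.random.default_rng(rng)
    n = mask.indicator.shape[0]
    return rng.normal(0.0, noise_sd, n) + in_mask_signal * mask.indicator
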