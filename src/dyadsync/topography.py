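"""Region-level still-face contrast.

Channel pairs are collapsed into 5 x 5 inter-brain region pairs (frontal,
central-parietal, occipital, left temporal, right temporal on each head)
and the combined still-face conditions (SF1, SF2) are tested against the
combined free-play/reunion conditions (FP1, FP2, RU) with one-sided
("less") paired t-tests per region pair and band -- 50 tests in all, FDR
corrected as one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .connectivity import SynchronyTable
from .stats import bh_adjust


@dataclass
class RegionMap:
    """Electrode grouping on each head.

    The default follows the five-region scheme frontal {F7, F8},
    central-parietal {C3, C4}, occipital {P7, P8}, left temporal {T7},
    right temporal {T8}; F3, F4, P3 and P4 are left unassigned by default
    (the grouping is configurable).  Regions must be disjoint and every
    listed electrode must exist in the montage.
    """

    regions: dict[str, tuple[str, ...]] = field(default_factory=lambda: {
        "frontal": ("F7", "F8"),
        "central_parietal": ("C3", "C4"),
        "occipital": ("P7", "P8"),
        "left_temporal": ("T7",),
        "right_temporal": ("T8",),
    })

    def validate(self, channel_labels: tuple[str, ...]) -> None:
        seen: set[str] = set()
        for name, chans in self.regions.items():
            if not chans:
                raise ValueError(f"region {name!r} has no electrodes")
            for ch in chans:
                if ch in seen:
                    raise ValueError(f"electrode {ch} in two regions")
                if ch not in channel_labels:
                    raise ValueError(
                        f"region {name!r} lists {ch}, absent from montage")
                seen.add(ch)

    def names(self) -> list[str]:
        return list(self.regions)


def region_pair_values(table: SynchronyTable, region_map: RegionMap,
                       condition_group: tuple[str, ...], band: str
                       ) -> pd.DataFrame:
    """Per-dyad region x region synchrony for a group of conditions.

    Per dyad the channel-pair matrices are first averaged over the
    conditions in the group (unweighted mean of condition means), then over
    all (mother electrode x infant electrode) combinations within each
    region pair.  Rows are dyads; columns are a MultiIndex
    (infant_region, mother_region).
    """
    region_map.validate(table.channel_labels)
    li = {ch: i for i, ch in enumerate(table.channel_labels)}
    names = region_map.names()
    dyads = list(dict.fromkeys(table.global_df["dyad"]))
    cols = pd.MultiIndex.from_product([names, names],
                                      names=["infant_region", "mother_region"])
    out = pd.DataFrame(index=pd.Index(dyads, name="dyad"), columns=cols,
                       dtype=float)
    import warnings as _warnings
    for dyad in dyads:
        mats = [table.pair_matrix(dyad, cond, band)
                for cond in condition_group]
        if any(np.all(np.isnan(m)) for m in mats):
            raise ValueError(
                f"dyad {dyad}: missing pair matrix for a grouped condition")
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean_mat = np.nanmean(np.stack(mats), axis=0)
            for ir in names:
                for mr in names:
                    rows = [li[ch] for ch in region_map.regions[mr]]
                    colsel = [li[ch] for ch in region_map.regions[ir]]
                    out.loc[dyad, (ir, mr)] = np.nanmean(
                        mean_mat[np.ix_(rows, colsel)])
    return out


def still_face_contrast(table: SynchronyTable,
                        region_map: RegionMap | None = None,
                        sf_conditions: tuple[str, ...] = ("SF1", "SF2"),
                        fp_conditions: tuple[str, ...] = ("FP1", "FP2", "RU"),
                        bands: tuple[str, ...] = ("theta", "alpha"),
                        fdr_family: str = "all") -> pd.DataFrame:
    """One-sided (SF < FP/RU) paired t-tests over all region pairs.

    Returns one row per (band, infant_region, mother_region) with the
    paired-t statistic, raw p and BH-FDR adjusted p.  ``fdr_family`` is
    ``"all"`` (both bands corrected together, the default: 5 x 5 x 2 = 50
    tests in one family) or ``"per_band"``.  All-zero differences give the
    uninformative t = 0, one-sided p = 0.5; a zero-variance nonzero
    difference is reported as degenerate with p of 0 or 1 by its sign.
    """
    region_map = region_map or RegionMap()
    rows = []
    for band in bands:
        sf = region_pair_values(table, region_map, sf_conditions, band)
        fp = region_pair_values(table, region_map, fp_conditions, band)
        both = sf.index.intersection(fp.index)
        if len(both) < 3:
            raise ValueError("need >= 3 dyads with both condition groups")
        for col in sf.columns:
            d = sf.loc[both, col].to_numpy() - fp.loc[both, col].to_numpy()
            note = ""
            if np.allclose(d.std(ddof=1), 0.0):
                if np.allclose(d, 0.0):
                    t, p = 0.0, 0.5
                else:
                    t = -np.inf if d.mean() < 0 else np.inf
                    p = 0.0 if d.mean() < 0 else 1.0
                note = "degenerate: zero-variance differences"
            else:
                res = sps.ttest_rel(sf.loc[both, col], fp.loc[both, col],
                                    alternative="less")
                t, p = float(res.statistic), float(res.pvalue)
            rows.append({"band": band, "infant_region": col[0],
                         "mother_region": col[1], "t": t,
                         "df": len(both) - 1, "p_raw": p, "p_fdr": np.nan,
                         "n": len(both), "note": note})
    df = pd.DataFrame(rows)
    if fdr_family == "all":
        df["p_fdr"] = bh_adjust(df["p_raw"])
    elif fdr_family == "per_band":
        for band in bands:
            sel = df.band == band
            df.loc[sel, "p_fdr"] = bh_adjust(df.loc[sel, "p_raw"])
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return df


def region_heatmap(results: pd.DataFrame, band: str, value: str = "t"):
    """Infant x mother region heat map of the contrast results."""
    import matplotlib.pyplot as plt

    sub = results[results.band == band]
    mat = sub.pivot(index="infant_region", columns="mother_region",
                    values=value)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(mat.index)), mat.index)
    ax.set_xlabel("mother region")
    ax.set_ylabel("infant region")
    ax.set_title(f"still-face contrast ({band}, {value})")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    return fig
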