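"""aDMP region construction and annotation-class summaries.

Called aDMPs are extended by a flank on both sides and overlapping
extensions are merged transitively into regions.  All coordinates are
0-based half-open: a site at ``pos`` with the default 100 bp flank
contributes ``[pos - 100, pos + 100)``, so an isolated aDMP yields a
region of exactly 200 bp.  Merged regions carry the member count, the
member gradient of maximum magnitude (sign retained) and the minimum
member p-value.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from admp.ioformats import BetaMatrix

log = logging.getLogger("admp.regions")

REGION_COLUMNS = ("chrom", "start", "end", "n_admps", "gradient", "min_p")


def make_regions(
    admps: pd.DataFrame, flank: int = 100, merge_touching: bool = False
) -> pd.DataFrame:
    """Merge flank-extended aDMPs into disjoint regions.

    ``admps`` is a site-indexed fit table with ``gradient`` and
    ``p_value`` columns (as produced by :func:`admp.sitefit.call_admps`
    after selection).  Extensions are clipped at coordinate 0 and never
    cross chromosomes.  By default only strictly overlapping extensions
    merge; book-ended (touching) intervals stay separate unless
    ``merge_touching`` is set.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if len(admps) == 0:
        return pd.DataFrame(columns=list(REGION_COLUMNS))
    df = pd.DataFrame(
        {
            "chrom": admps.index.get_level_values("chrom"),
            "pos": admps.index.get_level_values("pos").to_numpy(),
            "gradient": admps["gradient"].to_numpy(float),
            "p_value": admps["p_value"].to_numpy(float),
        }
    ).sort_values(["chrom", "pos"], kind="stable")

    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = np.maximum(grp["pos"].to_numpy() - flank, 0)
        ends = grp["pos"].to_numpy() + flank
        cur = None  # [start, end, gradients, pvals, n]
        for s, e, g, p in zip(starts, ends, grp["gradient"], grp["p_value"]):
            overlaps = cur is not None and (
                s < cur[1] or (merge_touching and s == cur[1])
            )
            if overlaps:
                cur[1] = max(cur[1], e)
                cur[2].append(g)
                cur[3].append(p)
            else:
                if cur is not None:
                    rows.append(_finish_region(chrom, cur))
                cur = [int(s), int(e), [g], [p]]
        if cur is not None:
            rows.append(_finish_region(chrom, cur))
    out = pd.DataFrame(rows, columns=list(REGION_COLUMNS))
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _finish_region(chrom: str, cur: list) -> dict:
    grads = np.asarray(cur[2])
    return {
        "chrom": chrom,
        "start": cur[0],
        "end": cur[1],
        "n_admps": len(grads),
        "gradient": float(grads[np.argmax(np.abs(grads))]),
        "min_p": float(min(cur[3])),
    }


def summarise_by_annotation(
    beta: BetaMatrix,
    annotations: Mapping[str, pd.DataFrame],
    background: str | None = "intergenic",
) -> pd.DataFrame:
    """Mean methylation of each site, grouped by annotation class.

    ``annotations`` maps class names to BED-style interval tables
    (chrom, start, end; 0-based half-open); earlier classes take
    precedence when a site falls in several (e.g. promoter over gene
    body), with a warning.  Sites in no interval go to ``background``
    (set it to None to drop them instead).  Returns one row per class
    with the number of sites, the class mean, and the per-site mean
    vector in the ``values`` column.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for cls, df in annotations.items():
        per_chrom: dict[str, IntervalTree] = {}
        for chrom, grp in df.groupby("chrom"):
            per_chrom[str(chrom)] = IntervalTree.from_tuples(
                zip(grp["start"], grp["end"])
            )
        trees[cls] = per_chrom

    site_means = np.nanmean(beta.values.to_numpy(), axis=1)
    chroms = beta.sites.get_level_values("chrom")
    poss = beta.sites.get_level_values("pos").to_numpy()
    classes = list(annotations)
    assigned: dict[str, list[float]] = {c: [] for c in classes}
    if background is not None:
        assigned.setdefault(background, [])
    n_conflicts = 0
    for chrom, pos, val in zip(chroms, poss, site_means):
        hits = [c for c in classes if trees[c].get(chrom) and trees[c][chrom].overlaps_point(pos)]
        if len(hits) > 1:
            n_conflicts += 1
        if hits:
            assigned[hits[0]].append(val)
        elif background is not None:
            assigned[background].append(val)
    if n_conflicts:
        log.warning(
            "%d sites matched several annotation classes; first class took precedence",
            n_conflicts,
        )
    rows = []
    for cls, vals in assigned.items():
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "annotation": cls,
                "n_sites": len(arr),
                "mean_beta": float(np.nanmean(arr)) if len(arr) else np.nan,
                "values": arr,
            }
        )
    return pd.DataFrame(rows).set_index("annotation")
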