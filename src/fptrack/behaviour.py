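"""Travel/search classification from FPT at the working ARS scale.

Fixes with long first-passage times at the working radius indicate high
residency (search); the bulk of short passage times indicates directed
flight, of which only the fastest half is kept as unambiguous travel.  The
intermediate band is excluded from habitat modelling: behaviour there is
indeterminate, and the model needs clean contrasts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("travel", "search", "excluded", "sitting", "undefined")


def classify(fpt_at_scale: np.ndarray, t_high: float = 300.0) -> np.ndarray:
    """Label each fix travel / search / excluded / undefined from its FPT.

    Fixes with FPT above ``t_high`` seconds are *search*.  Among fixes at or
    below ``t_high``, those at or below the median of that low band are
    *travel*; the rest are *excluded* (intermediate).  Undefined FPT (NaN)
    maps to *undefined*.  Ties at the median all become travel, so the split
    is deterministic and order-independent.
    """
    fpt = np.asarray(fpt_at_scale, dtype=float)
    defined = np.isfinite(fpt)
    if not defined.any():
        raise ValueError("all FPT values undefined; nothing to classify")
    labels = np.full(len(fpt), "undefined", dtype=object)
    search = defined & (fpt > t_high)
    low = defined & (fpt <= t_high)
    labels[search] = "search"
    if low.any():
        med = np.median(fpt[low])
        labels[low & (fpt <= med)] = "travel"
        labels[low & (fpt > med)] = "excluded"
    else:
        logger.warning("degenerate split: no fix at or below t_high=%.0f s, zero travel", t_high)
    return labels


def build_behaviour_table(fixes: pd.DataFrame, fpt_col: str = "fpt_s",
                          t_high: float = 300.0) -> pd.DataFrame:
    """Attach behaviour labels to a per-fix table.

    ``fixes`` must carry ``sitting`` (bool) and ``fpt_col`` (NaN at sitting
    fixes).  Sitting fixes keep the label *sitting*; the rest are classified
    from FPT at the working scale.
    """
    out = fixes.copy()
    out["label"] = "sitting"
    mask = ~out["sitting"].astype(bool).to_numpy()
    out.loc[mask, "label"] = classify(out.loc[mask, fpt_col].to_numpy(), t_high=t_high)
    return out


def table_to_geojson(table: pd.DataFrame) -> dict:
    """Labelled fixes as a GeoJSON FeatureCollection of points (for mapping)."""
    feats = []
    for _, row in table.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["lon"]), float(row["lat"])]},
            "properties": {
                "individual_id": row.get("individual_id"),
                "trip_id": row.get("trip_id"),
                "timestamp": str(row.get("timestamp")),
                "label": row["label"],
                "fpt_s": None if pd.isna(row.get("fpt_s")) else float(row["fpt_s"]),
            },
        })
    return {"type": "FeatureCollection", "features": feats}


def label_concordance(predicted: np.ndarray, truth: np.ndarray) -> dict:
    """Confusion matrix and balanced accuracy of travel/search vs. true modes.

    ``truth`` uses the generator's mode vocabulary (``transit``/``search``);
    only fixes predicted travel or search enter the comparison.  Balanced
    accuracy is the mean of per-true-class recall, so a labelling independent
    of the truth scores 0.5 regardless of class imbalance.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predicted vs {len(truth)} truth")
    keep = np.isin(predicted, ["travel", "search"])
    pred = np.where(predicted[keep] == "search", "search", "transit")
    tru = truth[keep]
    classes = ["transit", "search"]
    cm = np.zeros((2, 2), dtype=int)
    for i, tc in enumerate(classes):
        for j, pc in enumerate(classes):
            cm[i, j] = int(np.sum((tru == tc) & (pred == pc)))
    recalls = [cm[i, i] / cm[i].sum() for i in range(2) if cm[i].sum() > 0]
    bacc = float(np.mean(recalls)) if recalls else np.nan
    return {
        "confusion": pd.DataFrame(cm, index=classes, columns=classes),
        "balanced_accuracy": bacc,
        "n_compared": int(keep.sum()),
    }
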