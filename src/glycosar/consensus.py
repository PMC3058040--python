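"""Per-position consensus scoring of docked peptides.

After geometric culling, each surviving peptide carries one value per
scoring function (seven in the reference workflow: Shapegauss, Plp,
Chemgauss2, Chemgauss3, Chemscore, Screenscore and Goldscore). Goldscore
rewards good poses with large positive values, so it is negated to match the
others, after which a large negative value uniformly means a high rank.

The consensus step then summarizes, for every residue observed at an anchor
position, how the peptides carrying it scored: its frequency in the culled
set, plus the best (minimum), mean and standard deviation of each scoring
function — with seven functions, 1 + 3*7 = 22 parameters per residue. A PCA
on that summary matrix separates residues that are highly ranked, frequent
and consistent from the rest, and the selection rule picks the favourable
side of the first principal component.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chemometrics import PcaModel, fit_pca, preprocess

__all__ = [
    "SCORING_FUNCTIONS",
    "orient_scores",
    "summarize_position",
    "consensus_select",
]

#: Scoring functions produced by the rescoring stage, in canonical order.
SCORING_FUNCTIONS = (
    "Shapegauss",
    "Plp",
    "Chemgauss2",
    "Chemgauss3",
    "Chemscore",
    "Screenscore",
    "Goldscore",
)

#: Functions whose raw sign convention is "larger = better" and must be
#: negated so that all functions rank by minimization.
DEFAULT_FLIP = frozenset({"Goldscore"})


def orient_scores(table: pd.DataFrame, flip=DEFAULT_FLIP) -> pd.DataFrame:
    """Negate the named columns so every function scores lower = better."""
    unknown = set(flip) - set(table.columns)
    if unknown:
        raise ValueError(f"unknown scoring function(s) to flip: {sorted(unknown)}")
    out = table.copy()
    for col in flip:
        out[col] = -out[col]
    return out


def summarize_position(
    table: pd.DataFrame,
    peptides: dict[str, tuple[str, str]],
    position: str,
) -> pd.DataFrame:
    """Per-residue consensus statistics at one anchor position.

    For each residue occurring at ``position`` ("p260" or "p263") among the
    peptides in ``table`` (already oriented so lower = better), returns its
    frequency and, per scoring function, the best (minimum) score, the mean
    score and the sample standard deviation. Residues seen once get sd 0 so
    the summary matrix stays complete.
    """
    if position not in ("p260", "p263"):
        raise ValueError("position must be 'p260' or 'p263'")
    if table.empty:
        raise ValueError("empty score table")
    missing = [pid for pid in table.index if pid not in peptides]
    if missing:
        raise ValueError(f"peptides not in map: {missing[:10]}")
    idx = 0 if position == "p260" else 1
    residue = pd.Series(
        {pid: peptides[pid][idx] for pid in table.index}, name="residue"
    )
    grouped = table.groupby(residue)
    rows = {}
    for res, sub in grouped:
        row = {"frequency": len(sub)}
        for fn in table.columns:
            v = sub[fn].to_numpy(dtype=float)
            row[f"{fn}_best"] = float(v.min())
            row[f"{fn}_mean"] = float(v.mean())
            row[f"{fn}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        rows[res] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def _favourability_signs(columns) -> np.ndarray:
    """Desired direction per summary column: + for frequency (higher is
    better), - for best/mean (lower/more negative is better) and - for sd
    (less spread is better)."""
    signs = []
    for c in columns:
        if c == "frequency":
            signs.append(1.0)
        elif c.endswith("_sd"):
            signs.append(-1.0)
        else:
            signs.append(-1.0)
    return np.array(signs)


def consensus_select(
    summary: pd.DataFrame,
    n_components: int = 2,
    threshold: float = 0.0,
    cv: bool = False,
) -> tuple[list[str], PcaModel]:
    """Select favourable residues from the consensus-summary PCA.

    The summary matrix is mean-centered and UV-scaled, a PCA is fitted, and
    the first component is oriented (via its loadings) so that the positive
    direction means highly ranked + frequent + consistent. Residues whose
    PC1 score exceeds ``threshold`` are selected.
    """
    if len(summary) < 3:
        raise ValueError("need at least 3 residues to fit a consensus PCA")
    pre = preprocess(summary, center=True, uv_scale=True)
    model = fit_pca(pre, n_components=n_components, cv=cv)
    signs = _favourability_signs(pre.data.columns)
    orient = float(model.loadings["PC1"].to_numpy() @ signs)
    if orient < 0:
        model.loadings["PC1"] *= -1
        model.scores["PC1"] *= -1
    selected = list(model.scores.index[model.scores["PC1"] > threshold])
    return selected, model
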