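"""Biological response panels: binding inhibition and T-cell recognition.

The designed glycopeptides (2-21) and the unmodified reference glycopeptide
(1) were characterized by competitive MHC-binding assays (% inhibition of a
biotinylated marker peptide at 100 and 500 uM, against the murine Aq and
human DR4 class II MHC proteins) and by panels of Aq- and DR4-restricted
T-cell hybridomas. Hybridoma responses are ordinal categories given by the
antigen concentration needed to reach 10% of the reference's maximal IL-2
response: "-" (no response), "+" (150 uM) up to "++++++" (0.0064 uM).

This module ships the transcribed response tables as a package fixture,
encodes the ordinal categories on a log-concentration strength scale,
computes the table-level aggregates, and runs the combined-response PCA that
groups glycopeptides by their activity fingerprints.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .chemometrics import PcaModel, fit_pca

__all__ = [
    "TCELL_CONCENTRATIONS",
    "ResponsePanel",
    "load_response_panel",
    "encode_tcell",
    "table_aggregates",
    "response_pca",
]

#: Ordinal T-cell category -> threshold antigen concentration (uM).
TCELL_CONCENTRATIONS = {
    "+": 150.0,
    "++": 30.0,
    "+++": 6.0,
    "++++": 1.2,
    "+++++": 0.24,
    "++++++": 0.0064,
}

#: "No response" floor: one log-unit below the weakest category (10x the
#: highest tested concentration of 150 uM).
DEFAULT_FLOOR_UM = 1500.0

AQ_HYBRIDOMAS = ("22a1-7E", "HCQ.3", "HCQ.10", "HM1R.2", "HD13.9", "HNC.1")
DR4_HYBRIDOMAS = ("mDR17.2", "hDR11.2")


def _fixture_path(name: str) -> Path:
    return Path(importlib.resources.files("glycosar").joinpath("data", name))


def encode_tcell(symbol: str, floor_um: float = DEFAULT_FLOOR_UM) -> float:
    """Map an ordinal T-cell category to a strength = -log10(conc in uM).

    Stronger categories correspond to lower threshold concentrations, hence
    strictly larger strengths. "-" maps to the configurable floor
    concentration; "n.d." maps to NaN (missing).
    """
    s = str(symbol).strip()
    if s in {"n.d.", "nd", ""}:
        return float("nan")
    if s in {"-", "−"}:
        return -np.log10(floor_um)
    if s not in TCELL_CONCENTRATIONS:
        raise ValueError(f"unknown T-cell response symbol: {symbol!r}")
    return float(-np.log10(TCELL_CONCENTRATIONS[s]))


@dataclass
class ResponsePanel:
    """Transcribed binding and T-cell response data for peptides 1-21.

    ``table`` rows are peptide labels (strings "1".."21"); binding columns
    hold % inhibition (NaN where the peptide was classified inactive and not
    re-assayed), ``aq_active`` flags peptides with measured Aq binding, and
    T-cell columns hold the raw category symbols.
    """

    table: pd.DataFrame
    reference_id: str = "1"

    @property
    def designed_ids(self) -> list[str]:
        return [i for i in self.table.index if i != self.reference_id]

    def tcell_strengths(self, floor_um: float = DEFAULT_FLOOR_UM) -> pd.DataFrame:
        cols = [f"tc_{h}" for h in AQ_HYBRIDOMAS + DR4_HYBRIDOMAS]
        return self.table[cols].map(lambda s: encode_tcell(s, floor_um))


def load_response_panel(path=None) -> ResponsePanel:
    """Load the shipped (or a user-supplied) response-table fixture."""
    path = _fixture_path("tables1_2.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("peptide")
    num_cols = [c for c in df.columns if c.startswith(("aq_", "dr4_"))]
    active = ~df["aq_inh_100"].isin(["inactive"])
    out = df.copy()
    for c in num_cols:
        out[c] = pd.to_numeric(df[c].replace("inactive", np.nan), errors="coerce")
    out["aq_active"] = active
    bad = out[[c for c in num_cols]].stack()
    if ((bad < 0) | (bad > 100)).any():
        raise ValueError("% inhibition values must lie in [0, 100]")
    return ResponsePanel(out)


def table_aggregates(panel: ResponsePanel) -> dict[str, float]:
    """Aggregate checks over the transcribed tables.

    Reports the number of designed peptides with measured Aq binding, the
    min/max % inhibition among the designed peptides per protein and
    concentration, and the reference peptide's values.
    """
    if panel.table.empty:
        raise ValueError("empty response panel")
    t = panel.table
    designed = t.loc[panel.designed_ids]
    ref = t.loc[panel.reference_id]
    return {
        "n_designed": len(designed),
        "n_aq_active": int(designed["aq_active"].sum()),
        "aq_100_min": float(designed["aq_inh_100"].min()),
        "aq_100_max": float(designed["aq_inh_100"].max()),
        "aq_500_min": float(designed["aq_inh_500"].min()),
        "aq_500_max": float(designed["aq_inh_500"].max()),
        "dr4_500_min": float(designed["dr4_inh_500"].min()),
        "dr4_500_max": float(designed["dr4_inh_500"].max()),
        "ref_aq_100": float(ref["aq_inh_100"]),
        "ref_dr4_500": float(ref["dr4_inh_500"]),
    }


def encode_panel(
    panel: ResponsePanel,
    floor_um: float = DEFAULT_FLOOR_UM,
    inactive_inhibition: float = 0.0,
) -> pd.DataFrame:
    """Numeric peptide x response matrix for multivariate analysis.

    Binding columns: % inhibition with Aq-inactive peptides set to
    ``inactive_inhibition`` (they showed <30% in the screening assay).
    T-cell columns: category strengths; "n.d." stays missing here and is
    mean-imputed after scaling inside :func:`response_pca`.
    """
    t = panel.table
    X = pd.DataFrame(index=t.index)
    for c in ("aq_inh_100", "aq_inh_500"):
        X[c] = t[c].fillna(inactive_inhibition)
    for c in ("dr4_inh_100", "dr4_inh_500"):
        X[c] = t[c]
    strengths = panel.tcell_strengths(floor_um)
    for c in strengths.columns:
        X[c] = strengths[c]
    return X


def response_pca(
    panel: ResponsePanel,
    n_components: int = 3,
    n_groups: int = 4,
    floor_um: float = DEFAULT_FLOOR_UM,
    cv: bool = False,
) -> tuple[PcaModel, pd.Series]:
    """Combined-response PCA grouping peptides by activity fingerprint.

    The encoded response matrix is centered and UV-scaled with
    missing-tolerant statistics, missing cells are mean-imputed (zero after
    centering), a PCA is fitted, and the peptides are grouped by average-
    linkage hierarchical clustering of the first ``n_components`` scores.
    Peptides close in score space share similar binding and T-cell response
    fingerprints.
    """
    X = encode_panel(panel, floor_um)
    all_missing = X.isna().all(axis=1)
    if all_missing.any():
        import warnings

        warnings.warn(
            f"excluding peptides with all-missing responses: "
            f"{list(X.index[all_missing])}",
            stacklevel=2,
        )
        X = X.loc[~all_missing]
    means = X.mean(axis=0, skipna=True)
    sds = X.std(axis=0, ddof=1, skipna=True)
    if (sds.fillna(0) == 0).all():
        raise ValueError("all response columns are constant")
    keep = sds.index[sds.fillna(0) > 0]
    Xs = ((X[keep] - means[keep]) / sds[keep]).fillna(0.0)
    # sort for row-order invariance of the fit and clustering
    Xs = Xs.sort_index(key=lambda ix: ix.astype(str))
    model = fit_pca(Xs, n_components=min(n_components, len(Xs) - 1, len(keep)), cv=cv)
    T = model.scores.to_numpy()
    Z = linkage(pdist(T), method="average")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    groups = pd.Series(labels, index=model.scores.index, name="group")
    return model, groups
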