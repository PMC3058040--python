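"""Statistical molecular design: principal properties and D-optimal selection.

Candidate residues for each anchor position are characterized by
physicochemical descriptors, compressed by PCA into per-position principal
properties, and the full factorial of candidate peptides is then reduced to
a synthesis-sized subset with a D-optimal (Federov exchange) selection in
the principal-property space, so the subset spans the property space as
thoroughly as possible. A coverage check verifies that every residue level
appears often enough in the selection to support SAR modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import PcaModel, fit_pca, preprocess

__all__ = [
    "PrincipalPropertySpace",
    "CandidateDesign",
    "build_pp_space",
    "build_candidate_matrix",
    "federov_select",
    "coverage_check",
    "coverage_repair",
]


@dataclass
class PrincipalPropertySpace:
    """Per-position PCA over residue descriptors with per-residue scores."""

    models: dict[str, PcaModel]
    scores: dict[str, pd.DataFrame]  # position -> residue x component scores
    k: int

    def residue_scores(self, position: str, code: str) -> np.ndarray:
        table = self.scores[position]
        if code not in table.index:
            raise KeyError(f"residue {code!r} has no scores at {position}")
        return table.loc[code].to_numpy()[: self.k]


def build_pp_space(
    descriptors: dict[str, pd.DataFrame],
    n_components: int = 4,
    cv: bool = False,
) -> PrincipalPropertySpace:
    """Fit a PCA per position on residue descriptor tables.

    ``descriptors`` maps position name -> (residue x descriptor) DataFrame.
    Descriptors are mean-centered and UV-scaled before the fit; the first
    ``n_components`` score vectors become each residue's principal
    properties.
    """
    models, scores = {}, {}
    for pos, table in descriptors.items():
        if table.isna().any().any():
            bad = list(table.index[table.isna().any(axis=1)])
            raise ValueError(f"{pos}: residues with missing descriptors: {bad}")
        pre = preprocess(table, center=True, uv_scale=True)
        ncomp = min(n_components, len(table) - 1, pre.data.shape[1])
        model = fit_pca(pre, n_components=ncomp, cv=cv)
        models[pos] = model
        scores[pos] = model.scores
    k = min(m.n_components for m in models.values())
    return PrincipalPropertySpace(models=models, scores=scores, k=k)


@dataclass
class CandidateDesign:
    """A candidate set with its design model matrix and (optional) selection.

    ``model_matrix`` rows are [1, PP(p260) x k, PP(p263) x k] per candidate
    peptide (intercept plus main effects in principal properties, 2k+1
    columns). ``selected`` holds the chosen peptide ids after a D-optimal
    run, with ``log_det`` the log-determinant of X'X for the selection.
    """

    candidates: pd.DataFrame  # id, p260, p263
    model_matrix: pd.DataFrame
    k: int
    selected: list[str] = field(default_factory=list)
    log_det: float | None = None
    trace: list[float] = field(default_factory=list)


def build_candidate_matrix(
    space: PrincipalPropertySpace,
    p260_set,
    p263_set,
    k: int = 4,
) -> CandidateDesign:
    """Full-factorial candidates with principal-property model-matrix rows."""
    if k > space.k:
        raise ValueError(f"k={k} exceeds available components ({space.k})")
    rows, meta = [], []
    for a in p260_set:
        sa = space.residue_scores("p260", a)[:k]
        for b in p263_set:
            sb = space.residue_scores("p263", b)[:k]
            rows.append(np.concatenate([[1.0], sa, sb]))
            meta.append({"id": f"{a}_{b}", "p260": a, "p263": b})
    cand = pd.DataFrame(meta).set_index("id")
    cols = (
        ["intercept"]
        + [f"p260_PC{i + 1}" for i in range(k)]
        + [f"p263_PC{i + 1}" for i in range(k)]
    )
    mm = pd.DataFrame(rows, index=cand.index, columns=cols)
    return CandidateDesign(candidates=cand, model_matrix=mm, k=k)


def _log_det(X: np.ndarray, ridge: float) -> float:
    M = X.T @ X + ridge * np.eye(X.shape[1])
    sign, ld = np.linalg.slogdet(M)
    return ld if sign > 0 else -np.inf


def federov_select(
    design: CandidateDesign,
    N: int,
    n_starts: int = 20,
    seed: int = 0,
    ridge: float = 1e-8,
) -> CandidateDesign:
    """D-optimal subset selection by single-point Federov exchange.

    From each seeded random start of N candidates, repeatedly performs the
    single in/out swap that most increases det(X'X) until no swap improves
    it; the best of ``n_starts`` runs is returned. Ties in exchange deltas
    break toward the lowest candidate index, making seeded runs
    deterministic. A small ridge on X'X guards against singular subsets;
    when N is smaller than the number of model columns the information
    matrix is singular and the ridge is what makes the criterion finite.
    """
    F = design.model_matrix.to_numpy(dtype=float)
    n, p = F.shape
    if N > n:
        raise ValueError(f"cannot select {N} from {n} candidates")
    if N < p and ridge <= 0:
        raise ValueError("N below the number of model columns requires ridge > 0")
    if N == n:
        ld = _log_det(F, ridge)
        out = CandidateDesign(design.candidates, design.model_matrix, design.k)
        out.selected = list(design.model_matrix.index)
        out.log_det = ld
        out.trace = [ld]
        return out
    rng = np.random.default_rng(seed)
    best_sel, best_ld, best_trace = None, -np.inf, []
    for _ in range(n_starts):
        sel = np.sort(rng.choice(n, size=N, replace=False))
        in_set = np.zeros(n, dtype=bool)
        in_set[sel] = True
        ld = _log_det(F[in_set], ridge)
        trace = [ld]
        improved = True
        while improved:
            improved = False
            swap = None
            swap_ld = ld
            inside = np.flatnonzero(in_set)
            outside = np.flatnonzero(~in_set)
            for i in inside:
                for j in outside:
                    in_set[i], in_set[j] = False, True
                    cand_ld = _log_det(F[in_set], ridge)
                    in_set[i], in_set[j] = True, False
                    if cand_ld > swap_ld + 1e-12:
                        swap_ld = cand_ld
                        swap = (i, j)
            if swap is not None:
                i, j = swap
                in_set[i], in_set[j] = False, True
                ld = swap_ld
                trace.append(ld)
                improved = True
        if ld > best_ld:
            best_ld, best_sel, best_trace = ld, in_set.copy(), trace
    ids = list(design.model_matrix.index[best_sel])
    out = CandidateDesign(design.candidates, design.model_matrix, design.k)
    out.selected = ids
    out.log_det = best_ld
    out.trace = best_trace
    return out


@dataclass
class CoverageReport:
    counts: dict[str, dict[str, int]]
    min_count: int
    failing: list[tuple[str, str, int]]

    @property
    def passed(self) -> bool:
        return not self.failing


def coverage_repair(
    design: CandidateDesign,
    min_count: int = 2,
    ridge: float = 1e-8,
) -> CandidateDesign:
    """Swap candidates into the selection until every level meets min_count.

    Greedy: while some (position, level) is deficient, try replacing each
    selected candidate whose levels are over-represented with each
    unselected candidate carrying the deficient level, and commit the swap
    that loses the least log-determinant. An extension beyond plain
    D-optimality; off by default in the pipeline.
    """
    out = CandidateDesign(design.candidates, design.model_matrix, design.k)
    out.selected = list(design.selected)
    F = design.model_matrix
    while True:
        rep = coverage_check(out, min_count)
        if rep.passed:
            break
        pos, level, _count = rep.failing[0]
        sel = out.candidates.loc[out.selected]
        counts = rep.counts
        best = None
        for pid_out in out.selected:
            row = out.candidates.loc[pid_out]
            # removing pid_out must not create a new deficiency
            if any(
                counts[p][row[p]] - 1 < min_count for p in ("p260", "p263")
            ):
                continue
            for pid_in in out.candidates.index:
                if pid_in in out.selected:
                    continue
                if out.candidates.loc[pid_in, pos] != level:
                    continue
                trial = [p for p in out.selected if p != pid_out] + [pid_in]
                ld = _log_det(F.loc[trial].to_numpy(dtype=float), ridge)
                if best is None or ld > best[0]:
                    best = (ld, pid_out, pid_in)
        if best is None:
            raise ValueError(
                f"coverage repair stuck: cannot raise {pos} level {level!r} "
                f"to {min_count} without breaking another level"
            )
        _, pid_out, pid_in = best
        out.selected = [p for p in out.selected if p != pid_out] + [pid_in]
    out.log_det = _log_det(F.loc[out.selected].to_numpy(dtype=float), ridge)
    return out


def coverage_check(
    design: CandidateDesign,
    min_count: int = 2,
) -> CoverageReport:
    """Check that every residue level appears >= min_count times in the
    selection. Raises if the selection is empty or the requirement is
    infeasible for the selection size."""
    if not design.selected:
        raise ValueError("design has no selection")
    sel = design.candidates.loc[design.selected]
    counts: dict[str, dict[str, int]] = {}
    failing = []
    for pos in ("p260", "p263"):
        levels = sorted(design.candidates[pos].unique())
        if len(levels) * min_count > len(design.selected):
            raise ValueError(
                f"coverage infeasible at {pos}: {len(levels)} levels x "
                f"min_count {min_count} > selection size {len(design.selected)}"
            )
        c = sel[pos].value_counts().to_dict()
        counts[pos] = {lv: int(c.get(lv, 0)) for lv in levels}
        for lv in levels:
            if counts[pos][lv] < min_count:
                failing.append((pos, lv, counts[pos][lv]))
    return CoverageReport(counts=counts, min_count=min_count, failing=failing)
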