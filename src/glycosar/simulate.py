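"""Synthetic inputs with the statistical structure each pipeline stage assumes.

The docking, descriptor-calculation and assay software behind the original
workflow is proprietary and its outputs unpublished, so the pipeline is
exercised on generated data whose ground truth is known:

* score tables where each peptide's score is the sum of latent per-residue
  affinity contributions plus noise correlated across scoring functions;
* low-rank descriptor tables whose latent rank is recoverable by PCA;
* backbone poses perturbed from a reference at a controlled RMSD scale;
* binding responses from a known linear indicator model, clipped to the
  0-100 % inhibition range.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import SCORING_FUNCTIONS
from .library import PeptideVariant, enumerate_library
from .poses import PoseRecord

__all__ = [
    "GeneratorConfig",
    "gen_score_table",
    "gen_descriptor_table",
    "gen_poses",
    "gen_binding_responses",
    "reference_pose",
]


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic generators. ``seed`` is mandatory.

    ``latent_sd`` is the spread of true per-residue affinity contributions
    and ``noise_sd`` the scoring-noise scale, both in score units;
    ``correlation`` is the common-factor share of noise variance between
    scoring functions.
    """

    seed: int
    n_p260: int = 20
    n_p263: int = 20
    latent_mean: float = -30.0
    latent_sd: float = 3.0
    noise_sd: float = 2.0
    correlation: float = 0.6
    functions: tuple[str, ...] = SCORING_FUNCTIONS
    #: spread of planted per-level SAR effects (% inhibition units); matches
    #: the ~50-point gap between the best and worst residue levels in the
    #: transcribed binding tables
    sar_coef_sd: float = 15.0
    #: assay noise on % inhibition responses (replicate SDs in the tables
    #: are mostly 1-8)
    response_noise_sd: float = 5.0
    #: baseline per-level contribution so responses center near 50%
    sar_baseline: float = 25.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.latent_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must lie in [0, 1)")


def gen_score_table(
    config: GeneratorConfig,
    peptides: list[PeptideVariant] | None = None,
    advantage: dict[tuple[str, str], float] | None = None,
):
    """Score table with latent per-residue contributions and correlated noise.

    Each peptide's score under every function is
    ``latent(p260) + latent(p263) + noise`` where the noise shares a common
    factor across functions (variance fraction ``correlation``). Lower
    scores are better (the table is already oriented). ``advantage`` adds a
    planted extra contribution (negative = favourable) for chosen
    (position, residue) pairs, e.g. ``{("p260", "R3"): -5.0}``.

    Returns ``(table, truth)`` where ``truth`` maps (position, residue) to
    the true latent contribution including any planted advantage.
    """
    rng = np.random.default_rng(config.seed)
    if peptides is None:
        p260 = [f"A{i:03d}" for i in range(config.n_p260)]
        p263 = [f"B{i:03d}" for i in range(config.n_p263)]
        peptides = enumerate_library(p260, p263)
    codes260 = sorted({p.p260 for p in peptides})
    codes263 = sorted({p.p263 for p in peptides})
    lat260 = {
        c: config.latent_mean / 2 + config.latent_sd * rng.standard_normal()
        for c in codes260
    }
    lat263 = {
        c: config.latent_mean / 2 + config.latent_sd * rng.standard_normal()
        for c in codes263
    }
    truth = {("p260", c): v for c, v in lat260.items()}
    truth.update({("p263", c): v for c, v in lat263.items()})
    if advantage:
        for (pos, code), delta in advantage.items():
            truth[(pos, code)] += delta
            (lat260 if pos == "p260" else lat263)[code] += delta
    n, m = len(peptides), len(config.functions)
    base = np.array([lat260[p.p260] + lat263[p.p263] for p in peptides])
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, m))
    rho = config.correlation
    noise = config.noise_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * indep)
    values = base[:, None] + noise
    table = pd.DataFrame(
        values, index=[p.id for p in peptides], columns=list(config.functions)
    )
    return table, truth


def gen_descriptor_table(
    config: GeneratorConfig,
    n_residues: int,
    n_descriptors: int,
    latent_rank: int,
    noise_sd: float = 0.1,
    scale: float = 1.0,
    prefix: str = "R",
) -> pd.DataFrame:
    """Low-rank factor-model descriptor table: X = W H * scale + noise."""
    if latent_rank > n_descriptors:
        raise ValueError("latent_rank cannot exceed n_descriptors")
    rng = np.random.default_rng(config.seed)
    W = rng.standard_normal((n_residues, latent_rank))
    H = rng.standard_normal((latent_rank, n_descriptors))
    X = scale * (W @ H) + noise_sd * rng.standard_normal((n_residues, n_descriptors))
    return pd.DataFrame(
        X,
        index=[f"{prefix}{i:03d}" for i in range(n_residues)],
        columns=[f"d{j:02d}" for j in range(n_descriptors)],
    )


def reference_pose(n_residues: int = 8, first_resi: int = 260) -> PoseRecord:
    """An idealized extended backbone (N, CA, C per residue) reference pose."""
    rows = []
    for i in range(n_residues):
        resi = first_resi + i
        x0 = 3.8 * i
        rows.append({"resi": resi, "role": "N", "x": x0, "y": 0.0, "z": 0.0})
        rows.append({"resi": resi, "role": "CA", "x": x0 + 1.2, "y": 0.8, "z": 0.0})
        rows.append({"resi": resi, "role": "C", "x": x0 + 2.4, "y": 0.0, "z": 0.3})
    return PoseRecord("reference", pd.DataFrame(rows), stage="reference")


def gen_poses(
    reference: PoseRecord,
    n: int,
    perturbation_sd: float,
    seed: int,
    translation: np.ndarray | None = None,
    ids: list[str] | None = None,
):
    """Poses displaced from the reference by i.i.d. Gaussian atom noise.

    Per-atom displacements are N(0, sd^2) per coordinate, so the expected
    RMSD approaches ``sd * sqrt(3)`` for many atoms. With ``translation``
    the whole pose is instead shifted rigidly, giving RMSD = |t| exactly.
    Returns ``(poses, exact_rmsds)``.
    """
    if perturbation_sd < 0:
        raise ValueError("perturbation_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ref_xyz = reference.coords()[["x", "y", "z"]].to_numpy()
    meta = reference.coords()[["resi", "role"]]
    poses, rmsds = {}, {}
    for i in range(n):
        pid = ids[i] if ids else f"pose_{i:04d}"
        if translation is not None:
            xyz = ref_xyz + np.asarray(translation, dtype=float)
        else:
            xyz = ref_xyz + perturbation_sd * rng.standard_normal(ref_xyz.shape)
        atoms = meta.copy()
        atoms[["x", "y", "z"]] = xyz
        poses[pid] = PoseRecord(pid, atoms.reset_index(drop=True), stage="docked")
        rmsds[pid] = float(np.sqrt(np.mean(np.sum((xyz - ref_xyz) ** 2, axis=1))))
    return poses, rmsds


def gen_sar_dataset(config: GeneratorConfig, indicator_matrix: pd.DataFrame):
    """Planted indicator-model SAR dataset at the generator's default scales.

    Draws per-level effects beta ~ N(0, sar_coef_sd^2), adds the baseline
    contribution so responses center near 50 % inhibition, and generates
    ``y = X (beta + baseline) + noise`` via :func:`gen_binding_responses`.
    Returns ``(y, beta)`` with ``beta`` the centered planted effects.
    """
    rng = np.random.default_rng(config.seed)
    beta = rng.normal(0.0, config.sar_coef_sd, size=indicator_matrix.shape[1])
    y, _ = gen_binding_responses(
        indicator_matrix,
        beta + config.sar_baseline,
        config.response_noise_sd,
        seed=config.seed + 1,
    )
    return y, pd.Series(beta, index=indicator_matrix.columns)


def gen_binding_responses(
    indicator_matrix: pd.DataFrame,
    coefficients,
    noise_sd: float,
    seed: int,
    clip: tuple[float, float] = (0.0, 100.0),
):
    """Responses from a linear indicator model: y = X beta + noise, clipped.

    Clipping to the % inhibition range is a deliberate departure from pure
    linearity, mimicking the bounded assay readout. Returns
    ``(y, beta)`` with ``beta`` aligned to the indicator columns.
    """
    beta = np.asarray(coefficients, dtype=float)
    X = indicator_matrix.to_numpy(dtype=float)
    if beta.shape[0] != X.shape[1]:
        raise ValueError(
            f"coefficient length {beta.shape[0]} != n columns {X.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    y = X @ beta + noise_sd * rng.standard_normal(X.shape[0])
    y = np.clip(y, *clip)
    return pd.Series(y, index=indicator_matrix.index, name="response"), pd.Series(
        beta, index=indicator_matrix.columns
    )
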