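"""Diet-type and diet-diversity covariates from gut-content compositions.

Gut contents are proportions of prey categories per fish.  The diet-type
axis is a two-class Fisher discriminant between lake and stream fish on
Hellinger-transformed compositions; population means along the LD axis
describe how lake-like or stream-like a population's diet is.  Diet
diversity is the Gini-Simpson index of the population-summed gut
contents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DietTable",
    "DietLdaResult",
    "hellinger",
    "diet_lda",
    "gini_simpson",
]


@dataclass
class DietTable:
    """Per-fish prey-category proportions with habitat/population labels."""

    proportions: pd.DataFrame      # fish x prey category, rows sum to 1
    habitat: pd.Series             # "lake" | "stream" per fish
    population: pd.Series          # population key per fish

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy(dtype=float)
        if (p < 0).any():
            raise ValueError("negative prey proportions")
        sums = p.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            bad = self.proportions.index[np.abs(sums - 1) > 1e-8]
            raise ValueError(f"rows do not sum to 1: {list(bad)[:5]}")
        if not set(self.habitat.unique()) <= {"lake", "stream"}:
            raise ValueError("habitat labels must be lake/stream")

    @property
    def categories(self) -> list[str]:
        return list(self.proportions.columns)


def hellinger(table: DietTable | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Element-wise square root of compositional proportions.

    Since each row sums to one, every transformed row has unit sum of
    squares, making Euclidean geometry appropriate for the compositions.
    """
    if isinstance(table, DietTable):
        p = table.proportions.to_numpy(dtype=float)
    else:
        p = np.asarray(table, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportion")
    return np.sqrt(p)


@dataclass
class DietLdaResult:
    scores: pd.Series              # per-fish LD score, grand mean 0
    discriminant: np.ndarray       # unit vector in transformed space
    classification_rate: float     # training accuracy, nearest class mean
    population_means: pd.Series    # mean LD per population


def diet_lda(
    x: np.ndarray,
    habitat: pd.Series,
    population: pd.Series | None = None,
    ridge: float | None = None,
) -> DietLdaResult:
    """Two-class Fisher discriminant of (Hellinger-transformed) diets.

    w is proportional to Sw^-1 (mu_stream - mu_lake) with pooled
    within-class covariance Sw; a ridge eps*I (eps = 1e-8 tr(Sw)/p by
    default) handles the collinearity inherent to compositions.  Scores
    are centred on the grand mean and signed so the stream mean is
    positive.  Classification is by nearest class mean on the LD axis.
    """
    x = np.asarray(x, dtype=float)
    habitat = pd.Series(habitat).reset_index(drop=True).astype(str)
    labels = set(habitat.unique())
    if labels != {"lake", "stream"}:
        raise ValueError(f"need exactly the classes lake/stream, got {labels}")
    n, p = x.shape
    idx_l = habitat == "lake"
    idx_s = habitat == "stream"
    if idx_l.sum() < 2 or idx_s.sum() < 2:
        raise ValueError("each habitat class needs >= 2 fish")
    mu_l = x[idx_l].mean(axis=0)
    mu_s = x[idx_s].mean(axis=0)
    xl = x[idx_l] - mu_l
    xs = x[idx_s] - mu_s
    sw = (xl.T @ xl + xs.T @ xs) / (n - 2)
    if ridge is None:
        ridge = 1e-8 * np.trace(sw) / p
    try:
        w = np.linalg.solve(sw + ridge * np.eye(p), mu_s - mu_l)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-class covariance; increase the ridge") from exc
    w = w / np.linalg.norm(w)
    raw = x @ w
    scores = raw - raw.mean()
    if scores[idx_s.to_numpy()].mean() < 0:
        w, scores = -w, -scores
    # nearest class mean along the axis
    m_l = scores[idx_l.to_numpy()].mean()
    m_s = scores[idx_s.to_numpy()].mean()
    pred = np.where(np.abs(scores - m_s) < np.abs(scores - m_l),
                    "stream", "lake")
    rate = float((pred == habitat.to_numpy()).mean())
    scores = pd.Series(scores, name="diet_ld")
    if population is not None:
        pop = pd.Series(population).reset_index(drop=True).astype(str)
        pop_means = scores.groupby(pop).mean()
    else:
        pop_means = scores.groupby(habitat).mean()
    return DietLdaResult(scores=scores, discriminant=w,
                         classification_rate=rate,
                         population_means=pop_means)


def gini_simpson(values: np.ndarray | pd.Series) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2) of counts or proportions.

    Maximized at 1 - 1/k by the uniform distribution over k categories.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("negative values")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero input")
    p = v / total
    return float(1.0 - (p ** 2).sum())
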