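"""Size-controlled null comparison against randomized molecular subwebs.

Network metrics depend strongly on web dimensions, so the observation
web is never compared to the full molecular web directly: instead its
metrics are compared against the distribution obtained from random
subwebs of the molecular web with the same number of insect and plant
nodes (1,000 draws by default).  Subwebs that lose a node to an all-zero
row or column are rejected and redrawn, keeping node counts exact.
Percentile 95% intervals flag metrics where the observation web falls
outside the null.  A rare-link pruning operation supports the
sensitivity check that drops low-frequency links (count <= 2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from barcoweb.netmetrics import METRIC_NAMES, metric_set
from barcoweb.webs import BipartiteWeb


def sample_subweb(mol: BipartiteWeb, n_insects: int, n_plants: int,
                  rng: np.random.Generator,
                  max_attempts: int = 10_000) -> BipartiteWeb:
    """Uniform random induced subweb with exact node counts.

    Row and column subsets are drawn without replacement; a draw whose
    induced submatrix has an all-zero row or column is rejected and
    redrawn.  Raises ``RuntimeError`` after ``max_attempts`` rejections
    (a smaller target size usually fixes it).
    """
    m = mol.matrix
    if n_insects > m.shape[0] or n_plants > m.shape[1]:
        raise ValueError("requested subweb larger than the molecular web")
    a = m.to_numpy()
    for _ in range(max_attempts):
        rows = rng.choice(m.shape[0], size=n_insects, replace=False)
        cols = rng.choice(m.shape[1], size=n_plants, replace=False)
        sub = a[np.ix_(rows, cols)]
        if (sub.sum(axis=1) > 0).all() and (sub.sum(axis=0) > 0).all():
            sub_df = pd.DataFrame(sub, index=m.index[rows], columns=m.columns[cols])
            complexes = {c: mol.complexes[c] for c in sub_df.columns
                         if c in mol.complexes}
            return BipartiteWeb(sub_df, mol.level, complexes)
    raise RuntimeError(
        f"no valid subweb in {max_attempts} attempts; try a smaller target size")


@dataclass
class NullEnvelope:
    """Observed metrics vs the null distribution from randomized subwebs."""

    observed: dict[str, float]
    null_mean: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    outside_ci: dict[str, bool]
    n_draws: int
    seed: int | None
    n_na: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            name: {
                "observed": self.observed[name],
                "null_mean": self.null_mean[name],
                "ci_2.5": self.ci_low[name],
                "ci_97.5": self.ci_high[name],
                "outside_ci": self.outside_ci[name],
            }
            for name in self.observed
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_json(self, path=None) -> str:
        payload = {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "metrics": {
                name: {
                    "observed": self.observed[name],
                    "null_mean": self.null_mean[name],
                    "ci": [self.ci_low[name], self.ci_high[name]],
                    "outside_ci": self.outside_ci[name],
                    "n_na": self.n_na.get(name, 0),
                }
                for name in sorted(self.observed)
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def null_envelope(obs: BipartiteWeb, mol: BipartiteWeb, n_draws: int = 1000,
                  seed: int | None = None,
                  metrics: tuple[str, ...] | None = None,
                  n_restarts: int = 10,
                  max_attempts: int = 10_000) -> NullEnvelope:
    """Metric distribution over random size-matched subwebs plus flags.

    Draws ``n_draws`` subwebs of the molecular web matching the
    observation web's insect and plant node counts, scores each with the
    metric suite, and reports per-metric null mean, percentile 95% CI and
    whether the observation value falls outside it.  Fully reproducible
    under ``seed``.  Metrics that come out NaN in a draw are excluded
    from that metric's distribution (counts reported).
    """
    if obs.n_insects > mol.n_insects or obs.n_plants > mol.n_plants:
        raise ValueError("observation web larger than molecular web")
    names = METRIC_NAMES if metrics is None else tuple(metrics)
    rng = np.random.default_rng(seed)
    observed = metric_set(obs, seed=rng, n_restarts=n_restarts,
                          metrics=names).to_dict()
    draws: dict[str, list[float]] = {n: [] for n in names}
    n_na = {n: 0 for n in names}
    for _ in range(n_draws):
        sub = sample_subweb(mol, obs.n_insects, obs.n_plants, rng, max_attempts)
        values = metric_set(sub, seed=rng, n_restarts=n_restarts,
                            metrics=names).to_dict()
        for n in names:
            if math.isnan(values[n]):
                n_na[n] += 1
            else:
                draws[n].append(values[n])

    null_mean, lo, hi, outside = {}, {}, {}, {}
    for n in names:
        vals = np.asarray(draws[n])
        if len(vals) == 0:
            null_mean[n] = lo[n] = hi[n] = float("nan")
            outside[n] = False
            continue
        null_mean[n] = float(vals.mean())
        lo[n] = float(np.percentile(vals, 2.5))
        hi[n] = float(np.percentile(vals, 97.5))
        o = observed[n]
        outside[n] = bool(not math.isnan(o) and (o < lo[n] or o > hi[n]))
    return NullEnvelope(
        observed={n: observed[n] for n in names},
        null_mean=null_mean, ci_low=lo, ci_high=hi, outside_ci=outside,
        n_draws=n_draws, seed=seed, n_na=n_na,
    )


def prune_rare_links(web: BipartiteWeb, max_count: int = 2) -> BipartiteWeb:
    """Drop links with count <= ``max_count`` (then empty rows/columns).

    Raises ``ValueError`` when nothing survives.
    """
    m = web.matrix.where(web.matrix > max_count, 0)
    if (m.to_numpy() == 0).all():
        raise ValueError("pruning removed every link")
    pruned = BipartiteWeb(m, web.level, dict(web.complexes))
    return pruned
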