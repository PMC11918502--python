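"""Class-enumeration workflow: fit K = 1..Kmax and report selection criteria.

Four criteria are computed per K, following standard mixture-model
practice: (1) a minimum class size (default 5% of subjects) and
replication of the best log-likelihood across random starts; (2)
information criteria (AIC/BIC/aBIC) compared across K, with first
differences for a scree reading; (3) relative entropy (class separation);
(4) substantive interpretability — which a program cannot judge, so the
report highlights the "diminishing returns" elbow but never auto-selects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PanelDataset
from .mixture import EMConfig, FittedMixture, em_fit, relative_entropy, information_criteria

__all__ = ["EnumerationReport", "enumerate_classes"]


@dataclass
class EnumerationReport:
    """Per-K criteria table plus scree first differences and flags."""

    table: pd.DataFrame
    #: first differences of each IC (length rows-1), negative = improvement
    scree: pd.DataFrame
    #: smallest K after which every later BIC drop falls below
    #: elbow_fraction of the largest drop; None when Kmax < 3
    suggested_elbow: int | None
    elbow_fraction: float
    min_class_size: float
    fits: dict[int, FittedMixture]

    def render_scree(self) -> str:
        """Plain-text scree of BIC by K."""
        t = self.table
        lo, hi = t["bic"].min(), t["bic"].max()
        span = max(hi - lo, 1e-12)
        lines = []
        for _, row in t.iterrows():
            bar = "#" * (1 + int(round(40 * (row["bic"] - lo) / span)))
            lines.append(f"K={int(row['K'])}  bic={row['bic']:<14.2f} {bar}")
        return "\n".join(lines)


def enumerate_classes(
    data: PanelDataset,
    Kmax: int,
    config: EMConfig | None = None,
    min_class_size: float = 0.05,
    elbow_fraction: float = 0.20,
) -> EnumerationReport:
    """Fit 1..Kmax classes with the full multi-start protocol and tabulate
    all selection criteria.  A non-convergent K is flagged, not dropped."""
    if Kmax < 1:
        raise ValueError("Kmax must be >= 1")
    if config is None:
        config = EMConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    fits: dict[int, FittedMixture] = {}
    for K in range(1, Kmax + 1):
        cfg = EMConfig(**{**config.__dict__, "seed": int(rng.integers(2**31))})
        fit = em_fit(data, K, cfg)
        fits[K] = fit
        ics = information_criteria(fit.loglik, fit.n_params, data.n)
        min_prop = float(fit.params.pi.min())
        rows.append(
            {
                "K": K,
                "loglik": fit.loglik,
                "replicated": fit.ll_replicated if K > 1 else True,
                "converged": fit.converged,
                **ics,
                "entropy": relative_entropy(fit.posterior) if K >= 2 else np.nan,
                "min_class_prop": min_prop,
                "smallest_class_n": int(round(min_prop * data.n)),
                "meets_min_size": min_prop >= min_class_size,
            }
        )
    table = pd.DataFrame(rows)

    scree = pd.DataFrame(
        {
            "K_from": table["K"].to_numpy()[:-1],
            "K_to": table["K"].to_numpy()[1:],
            **{c: np.diff(table[c].to_numpy()) for c in ("aic", "bic", "abic")},
        }
    )

    suggested = None
    if Kmax >= 3:
        drops = -scree["bic"].to_numpy()  # positive = improvement
        largest = drops.max()
        if largest > 0:
            for i in range(len(drops)):
                if np.all(drops[i:] < elbow_fraction * largest):
                    suggested = int(table["K"].iloc[i])
                    break
    return EnumerationReport(
        table=table,
        scree=scree,
        suggested_elbow=suggested,
        elbow_fraction=elbow_fraction,
        min_class_size=min_class_size,
        fits=fits,
    )
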