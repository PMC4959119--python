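"""Leave-N-subjects-out stability of the coupled decomposition.

Each repeat removes a uniformly random fraction of subjects (5% by
default), reruns the coupled ICA with a derived seed, and matches the
subsample sources to the full-data sources by optimal |correlation|
assignment over the shared feature space.  A component is called stable
when its mean matched |correlation| across repeats reaches the stability
threshold; the per-modality percentage of stable components is the
headline figure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import run_para_ica, match_components
from .datatypes import ParaIcaResult

logger = logging.getLogger(__name__)

__all__ = ["StabilityReport", "loo_stability"]


@dataclass
class StabilityReport:
    per_component: pd.DataFrame  # modality, component, mean_abs_corr, stable
    percent_stable: dict  # modality -> percent of components stable
    mean_correlation: dict  # modality -> mean matched |corr| across components
    repeats_done: int
    holdout_frac: float
    tau_stab: float

    def __post_init__(self) -> None:
        for mod in self.percent_stable:
            sub = self.per_component[self.per_component["modality"] == mod]
            expect = 100.0 * sub["stable"].sum() / len(sub)
            if abs(expect - self.percent_stable[mod]) > 1e-9:
                raise ValueError("percent_stable inconsistent with per-component flags")

    def to_frame(self) -> pd.DataFrame:
        return self.per_component.copy()


def loo_stability(
    X_gene: np.ndarray,
    X_brain: np.ndarray,
    fusion_config: dict,
    holdout_frac: float = 0.05,
    repeats: int = 10,
    tau_stab: float = 0.8,
    seed: int = 0,
    full_result: ParaIcaResult | None = None,
) -> StabilityReport:
    """Leave-``holdout_frac``-of-subjects-out stability of the fused components.

    ``fusion_config`` is the keyword dict passed to :func:`run_para_ica`
    (it must contain ``K_gene`` and ``K_brain``).  The full-data reference
    decomposition is computed once (or supplied via ``full_result``); each
    repeat refits on a random subsample and matched source correlations
    are accumulated per component.
    """
    n = X_gene.shape[0]
    n_hold = int(round(holdout_frac * n))
    if n_hold < 1:
        raise ValueError(f"holdout {holdout_frac} of {n} subjects removes nobody")
    if repeats < 2:
        raise ValueError("need at least 2 repeats")
    rng = np.random.default_rng(seed)

    cfg = dict(fusion_config)
    base_seed = cfg.pop("seed", seed)
    if full_result is None:
        full_result = run_para_ica(X_gene, X_brain, seed=base_seed, **cfg)
    ref = {"gene": full_result.gene_model.sources, "brain": full_result.brain_model.sources}
    k = {m: ref[m].shape[0] for m in ref}
    corr_acc = {m: np.zeros(k[m]) for m in ref}

    done = 0
    for rep in range(repeats):
        drop = rng.choice(n, size=n_hold, replace=False)
        keep = np.setdiff1d(np.arange(n), drop)
        rep_seed = int(rng.integers(2**31))
        try:
            res = run_para_ica(X_gene[keep], X_brain[keep], seed=rep_seed, **cfg)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("stability repeat %d failed (%s); skipped", rep, exc)
            continue
        for mod, model in (("gene", res.gene_model), ("brain", res.brain_model)):
            _, _, corrs = match_components(ref[mod], model.sources)
            corr_acc[mod] += np.nan_to_num(corrs)
        done += 1
    if done < 2:
        raise RuntimeError(f"only {done} stability repeats succeeded; need at least 2")

    rows = []
    percent: dict[str, float] = {}
    meancorr: dict[str, float] = {}
    for mod in ("gene", "brain"):
        means = corr_acc[mod] / done
        stable = means >= tau_stab
        for c in range(k[mod]):
            rows.append({"modality": mod, "component": c,
                         "mean_abs_corr": float(means[c]), "stable": bool(stable[c])})
        percent[mod] = 100.0 * stable.sum() / k[mod]
        meancorr[mod] = float(means.mean())
    return StabilityReport(
        per_component=pd.DataFrame(rows),
        percent_stable=percent,
        mean_correlation=meancorr,
        repeats_done=done,
        holdout_frac=holdout_frac,
        tau_stab=tau_stab,
    )
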