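"""End-to-end pipeline helpers combining simulation, selection, training."""

from __future__ import annotations

from dataclasses import dataclass

from .classify import CVReport, ClassifierModel, train
from .feature_select import select_top, snp_association_scores
from .hapmap_io import BreedTable, GenotypeMatrix
from .synthdata import SimulationConfig, SimulationTruth, simulate_breeds

__all__ = ["PanelCVResult", "panel_cv_benchmark"]


@dataclass
class PanelCVResult:
    """Outcome of one simulate -> rank -> panel -> train experiment."""

    G: GenotypeMatrix
    breeds: BreedTable
    truth: SimulationTruth
    model: ClassifierModel
    report: CVReport
    panel_size: int


def panel_cv_benchmark(
    n_breeds: int = 10,
    n_per_breed: int = 20,
    n_snps: int = 2000,
    fst: float = 0.15,
    panel_size: int = 500,
    score_method: str = "chi2",
    algorithm: str = "rf",
    cv_scheme: str = "kfold:5",
    seed: int = 1,
    alpha: float = 2.0,
) -> PanelCVResult:
    """Simulate a multi-breed dataset and run the discrimination pipeline.

    Breeds are drawn under Balding–Nichols at the given FST, SNPs are
    ranked by breed association, the top ``panel_size`` form the panel,
    and a classifier is trained under cross-validation. Returns the
    fitted model plus the pooled CV report (accuracy, kappa, macro AUC).
    """
    config = SimulationConfig(
        n_breeds=n_breeds,
        n_per_breed=n_per_breed,
        n_snps=n_snps,
        fst=fst,
        seed=seed,
    )
    G, breeds, _, truth = simulate_breeds(config)
    scores = snp_association_scores(G, breeds, method=score_method, seed=seed)
    panel = select_top(scores, count=min(panel_size, len(scores.table)))
    model, report = train(
        G,
        breeds,
        panel,
        algorithm=algorithm,
        cv_scheme=cv_scheme,
        seed=seed,
        alpha=alpha,
    )
    return PanelCVResult(G, breeds, truth, model, report, len(panel))
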