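"""Shared planted study designs used across test modules."""

from tissuespec import synthetic_data as sd


def planted_config(cv: float, seed: int = 0, n_genes: int = 2000) -> sd.SimConfig:
    """Reference planted design: 10 specific + 5 enhanced_1 + 5 enhanced_2
    genes at fold 8 targeting the atrial appendage, plus 10 DEG genes,
    across 20 tissues x 30 samples."""
    return sd.SimConfig(
        n_tissues=20,
        samples_per_tissue=30,
        n_genes=n_genes,
        cv=cv,
        seed=seed,
        planted_specific=tuple(sd.PlantedSpecific(g, 0, 8.0) for g in range(10)),
        planted_enhanced=(
            tuple(sd.PlantedEnhanced(10 + i, 0, (2 + i,), 8.0, 4.0) for i in range(5))
            + tuple(
                sd.PlantedEnhanced(15 + i, 0, (2 + i, 8 + i), 8.0, 4.0)
                for i in range(5)
            )
        ),
        planted_deg=tuple(sd.PlantedDeg(40 + i, 4.0) for i in range(10)),
    )


def planted_truth(config: sd.SimConfig) -> dict[str, str]:
    """Expected call per planted gene id for the focal (first) tissue."""
    ids = sd.gene_ids(config)
    truth: dict[str, str] = {}
    for p in config.planted_specific:
        truth[ids[p.gene]] = "specific"
    for p in config.planted_enhanced:
        truth[ids[p.gene]] = f"enhanced_except_{len(p.exceptions)}"
    return truth
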