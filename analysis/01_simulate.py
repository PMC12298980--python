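#!/usr/bin/env python
"""Generate the default synthetic study used by the downstream analyses.

Writes a full study directory (functions, metadata, prokaryote / fungus /
plant communities with taxonomies and trees, plant traits, raw microbial
activity, latent drivers, truth record) under results/study/.
"""

from pathlib import Path

from emfkit.design import StudyDesign
from emfkit.io import write_study
from emfkit.synthetic import generate_study

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    design = StudyDesign(seed=SEED)
    study = generate_study(design)
    write_study(study, OUT)
    print(f"study written to {OUT}")
    print(f"  plots: {design.n_plots} ({design.n_groups} groups x {design.plots_per_group})")
    for dom, ct in study.communities.items():
        print(f"  {dom}: {ct.shape[0]} taxa")
    print(f"  planted fungal indicators: {len(study.truth['taxa']['fungus']['indicator_ids'])}")


if __name__ == "__main__":
    main()
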