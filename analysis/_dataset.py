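"""Shared study design for the analysis scripts.

One synthetic screen: a 20-embryo wild-type cohort plus eight perturbed
pseudo-genes covering the phenotype classes the pipeline must separate
(asynchrony collapse, partial reduction, global slowdown, variance
buffering, early arrest, marker knockout, position shift, and a null).
Recordings land under scratch/ (they are bulky); summary tables under
results/.
"""

from pathlib import Path

from lineatime.simulate import (
    PerturbationSpec,
    make_template,
    simulate_screen_dataset,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "screen_data"
RESULTS = ROOT / "results"

SEED = 20240907
N_WILDTYPE = 20
REPLICATES = 3


def gene_specs(template):
    all_pairs = dict.fromkeys(template.async_pairs, 0.1)
    return {
        "ads-collapse": PerturbationSpec(ads_factor=all_pairs),
        "ads-partial": PerturbationSpec(ads_factor={"P3": 0.4, "ABala": 0.4}),
        "slowdown": PerturbationSpec(slowdown=1.35),
        "buffering": PerturbationSpec(variance_inflation={"AB": 4.0}),
        "arrest": PerturbationSpec(arrest_frame=70),
        "marker-loss": PerturbationSpec(expression_knockout="E"),
        "mispositioned": PerturbationSpec(position_shift={"ABal": (0.5, 0.3, 0.2)}),
        "null-gene": PerturbationSpec(),
    }


def build_dataset():
    template = make_template()
    wildtype, perturbed, truth = simulate_screen_dataset(
        template,
        gene_specs=gene_specs(template),
        n_wildtype=N_WILDTYPE,
        replicates=REPLICATES,
        seed=SEED,
    )
    return template, wildtype, perturbed, truth


def all_recordings(wildtype, perturbed):
    return wildtype + [r for recs in perturbed.values() for r in recs]
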