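import pytest

from polypat import panel as panel_mod
from polypat import paternity, simulate


@pytest.fixture(scope="session")
def default_panel():
    return panel_mod.synthetic_panel()


@pytest.fixture(scope="session")
def small_run(default_panel):
    """Noise-free polycross at reduced seed count, with assignments."""
    design = simulate.make_design()
    truth = simulate.simulate_matings(
        design, simulate.MatingParams(), seeds_per_plant=4, rng_seed=11
    )
    calls = simulate.genotype_offspring(truth, default_panel, rng_seed=12)
    roster = design.roster()
    mother_map = dict(zip(roster["plant_id"], roster["genotype"]))
    assignments, summary = paternity.assign_batch(calls, default_panel, mother_map)
    return {
        "design": design,
        "truth": truth,
        "calls": calls,
        "mother_map": mother_map,
        "assignments": assignments,
        "summary": summary,
    }


def random_homozygous_panel(rng, n_genotypes=8, n_markers=12):
    """Random all-inbred panel; genotype calls are homozygous everywhere."""
    markers = [
        panel_mod.SNPMarker(f"m{j:02d}", frozenset(("A", "G")))
        for j in range(n_markers)
    ]
    codes = rng.integers(2, size=(n_genotypes, n_markers))
    genotypes = []
    for i in range(n_genotypes):
        calls = {}
        for j, m in enumerate(markers):
            base = m.allele_pair[codes[i, j]]
            calls[m.marker_id] = (base, base)
        genotypes.append(
            panel_mod.GenotypeRecord(genotype_id=f"G{i + 1}", calls=calls)
        )
    return panel_mod.GenotypePanel(markers=markers, genotypes=genotypes)
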