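import pytest

from fwsolv.freewilson import fit
from fwsolv.rgroups import CoreScaffold, build_design_matrix, decompose
from fwsolv.synth import generate_series, toy_series_spec

# wide-tolerance grid reused across fit tests; includes a negligible penalty
# so noise-free series are fit essentially unregularized
ALPHA_GRID = (1e-8, 1e-4, 1e-2, 1.0, 100.0)


@pytest.fixture(scope="session")
def phenyl_scaffold() -> CoreScaffold:
    """Minimal two-site para-phenylene core for hand-checkable decompositions."""
    return CoreScaffold("[*:1]c1ccc([*:2])cc1")


@pytest.fixture(scope="session")
def noisefree_bundle():
    """Noise-free toy series with its decomposition, design matrix and fit."""
    spec = toy_series_spec(n_ligands=40, noise_sd=0.0, seed=11)
    dataset, truth = generate_series(spec)
    assignments = [
        decompose(smi, spec.scaffold, ligand_id=lid)
        for smi, lid in zip(dataset.records.smiles, dataset.records.ligand_id)
    ]
    assert all(a.matched for a in assignments)
    design = build_design_matrix(assignments)
    y = dataset.records.set_index("ligand_id").loc[design.ligand_ids, "pic50"].to_numpy()
    model = fit(design, y, alpha_grid=ALPHA_GRID)
    return {
        "spec": spec,
        "dataset": dataset,
        "truth": truth,
        "assignments": assignments,
        "design": design,
        "y": y,
        "model": model,
    }
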