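import numpy as np
import pytest

from neuriteflow import (MorphologySpec, SimulationParams, build_unit_graph,
                         decompose, generate_morphology)


@pytest.fixture(scope="session")
def chain_morphology():
    return generate_morphology(MorphologySpec(n_bifurcations=0, seed=1))


@pytest.fixture(scope="session")
def y_morphology():
    return generate_morphology(MorphologySpec(n_bifurcations=1, seed=2))


@pytest.fixture(scope="session")
def y_structure(y_morphology):
    return decompose(y_morphology, max_pipe_sections=50)


@pytest.fixture(scope="session")
def pipe_graph(y_structure):
    unit = next(u for u in y_structure.units if u.kind == "pipe")
    return build_unit_graph(unit)


@pytest.fixture(scope="session")
def bif_graph(y_structure):
    unit = next(u for u in y_structure.units if u.kind == "bifurcation")
    return build_unit_graph(unit)


@pytest.fixture()
def params():
    return SimulationParams()


def make_chain_graph(n_nodes: int, length: float):
    """Hand-built 1D chain as a TemplateGraph: one node per section.

    Used as a degenerate domain where the solver's discrete operators reduce
    to classical 1D finite differences.
    """
    from neuriteflow.graph_build import TemplateGraph

    x = np.linspace(0.0, length, n_nodes)
    pos = np.column_stack([np.zeros(n_nodes), np.zeros(n_nodes), x])
    edges = np.column_stack([np.arange(n_nodes - 1), np.arange(1, n_nodes)])
    roles = np.array(["inlet"] + ["interior"] * (n_nodes - 2) + ["outlet"])
    return TemplateGraph(
        kind="pipe", unit_id=0, positions=pos,
        node_section=np.arange(n_nodes),
        node_template_index=np.zeros(n_nodes, dtype=np.int64),
        rfrac=np.zeros(n_nodes),
        node_radii=np.ones(n_nodes),
        edges=edges, roles=roles,
        interface_ids=np.array([None] * n_nodes, dtype=object),
        section_centers=pos,
        section_tangents=np.tile([0.0, 0.0, 1.0], (n_nodes, 1)),
        section_radii=np.ones(n_nodes),
        section_upstream=np.arange(-1, n_nodes - 1),
        inlet_section=0, outlet_sections=[n_nodes - 1],
    )
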