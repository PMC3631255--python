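import pytest

from motifmatch import LinkTypeRegistry, TypedGraph, build_worked_example, parse_motif


@pytest.fixture
def reg_abc():
    """A, B directed; C undirected (the worked-example registry)."""
    return LinkTypeRegistry([("A", True), ("B", True), ("C", False)])


@pytest.fixture
def reg_a():
    return LinkTypeRegistry([("A", True)])


@pytest.fixture
def reg_x():
    return LinkTypeRegistry([("X", False)])


@pytest.fixture
def worked():
    return build_worked_example()


@pytest.fixture
def worked_alt():
    return build_worked_example(alternative=True)


def complete_undirected(n, type_name="X"):
    reg = LinkTypeRegistry([(type_name, False)])
    g = TypedGraph(reg)
    nodes = [str(i) for i in range(n)]
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            g.add_link(u, v, type_name)
    return reg, g


def complete_directed(n, type_name="A"):
    reg = LinkTypeRegistry([(type_name, True)])
    g = TypedGraph(reg)
    nodes = [str(i) for i in range(n)]
    for u in nodes:
        for v in nodes:
            if u != v:
                g.add_link(u, v, type_name)
    return reg, g


def out_star(n_leaves, type_name="A", extra_types=(("C", False),)):
    reg = LinkTypeRegistry([(type_name, True), *extra_types])
    g = TypedGraph(reg)
    for i in range(n_leaves):
        g.add_link("c", f"l{i}", type_name)
    return reg, g
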