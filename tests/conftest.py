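import pytest

from tdnkit import (
    EnergyModel,
    GeneratorSpec,
    ModifiedStrand,
    Nucleotide,
    fraying_landscape,
    generate_design,
    retained_duplex,
)


def make_strand(name, seq, sugars=None, linkages=None, loci=None):
    """Build a strand from compact strings: sugars like 'DDRRLM', linkages 'oos s'."""
    code2sugar = {"D": "DNA", "R": "RNA", "L": "LNA", "M": "OME"}
    n = len(seq)
    sugars = sugars or "D" * n
    nts = []
    for i, base in enumerate(seq):
        if linkages is None:
            link = None if i == n - 1 else "PO"
        else:
            link = None if i == n - 1 else ("PS" if linkages[i] == "s" else "PO")
        nts.append(Nucleotide(base=base, sugar=code2sugar[sugars[i]], linkage3=link))
    return ModifiedStrand(name=name, nts=tuple(nts), loci=loci or {})


@pytest.fixture(scope="session")
def default_spec():
    return GeneratorSpec(seed=1)


@pytest.fixture(scope="session")
def default_design(default_spec):
    return generate_design(default_spec)


@pytest.fixture(scope="session")
def default_fraying(default_design):
    return fraying_landscape(retained_duplex(default_design))


@pytest.fixture()
def zero_model():
    """Energy model with every contribution switched off (flat landscapes)."""
    zero = {k: (0.0, 0.0) for k in "AA AT TA CA GT CT GA CG GC GG AC AG TC TG CC TT".split()}
    zero_h = {k.replace("T", "U") if False else k: (0.0, 0.0) for k in
              "AA AC AG AU CA CC CG CU GA GC GG GU UA UC UG UU".split()}
    return EnergyModel(
        temperature=310.15,
        salt_mM=1000.0,
        mod_increments={"LNA": 0.0, "OME": 0.0},
        ps_increment=0.0,
        init_dG=0.0,
        tether_init_dG=0.0,
        bm_plateau_dG=0.0,
        nn_dna=zero,
        nn_hybrid=zero_h,
    )
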