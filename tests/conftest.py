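import pytest

from cocryst.mep import InteractionSite, MoleculeSites


def sites_from_params(molecule_id, alphas, betas):
    """Molecule with explicit alpha/beta parameters (ESP fields unused)."""
    donors = [InteractionSite(f"{molecule_id}_d{i}", "donor", 0.0, a)
              for i, a in enumerate(alphas)]
    acceptors = [InteractionSite(f"{molecule_id}_a{i}", "acceptor", 0.0, b)
                 for i, b in enumerate(betas)]
    return MoleculeSites(molecule_id, donors, acceptors)


@pytest.fixture
def worked_pair():
    """The 1-donor/1-acceptor worked example: api (a=5, b=4), cf (a=3, b=2).

    Hand enumeration: E_1 = -20, E_2 = -6, E_cc(A) = -(5*2 + 3*4) = -22,
    E_cc(B) = -(5*4 + 3*2) = -26, so dE(A) = +4 and dE(B) = 0.
    """
    api = sites_from_params("api", [5.0], [4.0])
    cf = sites_from_params("cf", [3.0], [2.0])
    return api, cf
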