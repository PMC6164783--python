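import warnings

import pytest

from kinafam import alignment_phylo, kinase_scan, promoter_scan, synthetic_data


@pytest.fixture(scope="session")
def elements():
    return promoter_scan.packaged_element_table()


@pytest.fixture(scope="session")
def toy(elements):
    """Default synthetic genome (seed 0, zero Ct noise) with promoters
    planted and the Ct table simulated."""
    config = synthetic_data.SynthConfig(seed=0, ct_noise_sd=0.0)
    toy = synthetic_data.generate_toy_genome(config, elements)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        promoters, _ = synthetic_data.plant_promoter_elements(toy, elements)
    ct_table, _ = synthetic_data.simulate_ct_table(toy)
    toy.promoters = promoters
    toy.ct_table = ct_table
    return toy


@pytest.fixture(scope="session")
def family_proteins(toy):
    return {r.id: r.sequence
            for r in toy.proteins if not r.id.startswith("decoy")}


@pytest.fixture(scope="session")
def family_tree(toy, family_proteins):
    """Progressive MSA + NJ tree of family members and references."""
    seqs = dict(family_proteins)
    seqs.update({r.id: r.sequence for r in toy.references})
    msa = alignment_phylo.progressive_msa(seqs)
    tree = alignment_phylo.neighbor_joining(alignment_phylo.p_distance(msa))
    return msa, tree


@pytest.fixture(scope="session")
def truth_groups(toy):
    return dict(zip(toy.truth.members.gene_id, toy.truth.members.group))


@pytest.fixture(scope="session")
def tloops(family_proteins):
    return {gid: kinase_scan.find_signature(seq).tloop_type
            for gid, seq in family_proteins.items()}
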