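from __future__ import annotations

import numpy as np
import pytest

import numt_sieve as ns


@pytest.fixture(scope="session")
def community():
    """A small clean community: 60 codon-clean 658-nt descendants of one
    ancestor (deterministic)."""
    return ns.generate_synthetic_community(60, seed=11)


@pytest.fixture(scope="session")
def community_hmm(community):
    """Profile HMM built from the community's own longest-ORF amino-acid
    sequences (all equal length, so the alignment is trivially ungapped)."""
    rows = []
    for rec in community:
        orf = ns.longest_orf(ns.find_orfs(rec, ns.INVERTEBRATE_MITO))
        rows.append(ns.aligned_record(rec.id, orf.aa_seq, "aa"))
    return ns.build_profile_hmm(ns.Alignment(rows))


def random_profile_hmm(M: int, rng: np.random.Generator) -> ns.ProfileHmm:
    """A dense random model with strictly positive probabilities."""
    return ns.ProfileHmm(
        M=M,
        match_emit=rng.dirichlet(np.ones(20) * 0.5, size=M),
        insert_emit=rng.dirichlet(np.ones(20) * 0.5, size=M + 1),
        trans=np.hstack([
            rng.dirichlet(np.ones(3), size=M + 1),
            rng.dirichlet(np.ones(2), size=M + 1),
            rng.dirichlet(np.ones(2), size=M + 1),
        ]),
        null_freqs=rng.dirichlet(np.ones(20)),
    )
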