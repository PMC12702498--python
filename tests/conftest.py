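import numpy as np
import pytest

from ampedit import AlleleSpec, ReadSimConfig, make_amplicon, simulate_reads
from ampedit.refs import GuideSite

SPACER = "GACCTGATCGGATCAATCGA"  # 20 nt, 5' G


@pytest.fixture(scope="session")
def planted_amplicon():
    """200-bp amplicon with one NGG protospacer planted at position 60."""
    ref = make_amplicon(200, seed=7, planted_sites=[(SPACER, "NGG", "+", 60)])
    guide = GuideSite(
        role="pegRNA", spacer=SPACER, strand="+", start=60, pam="NGG",
        amplicon_id=ref.id,
    )
    guide.validate_against(ref)
    return ref, guide


def random_amplicon_with_guide(seed, length=180, pos=60, strand="+"):
    """A fresh random amplicon with an NGG site; returns (ref, guide)."""
    rng = np.random.default_rng(seed)
    spacer = "G" + "".join(rng.choice(list("ACGT"), 19))
    ref = make_amplicon(length, seed=seed, planted_sites=[(spacer, "NGG", strand, pos)])
    guide = GuideSite(
        role="pegRNA", spacer=spacer, strand=strand, start=pos, pam="NGG",
        amplicon_id=ref.id,
    )
    guide.validate_against(ref)
    return ref, guide


def exact_mixture_reads(ref, alleles, n_reads=300, seed=0, error_rate=0.0):
    return simulate_reads(
        ref, alleles,
        ReadSimConfig(n_reads=n_reads, error_rate=error_rate, seed=seed),
    )
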