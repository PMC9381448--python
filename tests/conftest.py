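import pytest

from clipsplice.as_events import ASEvent
from clipsplice.synthetic import SimSpec, gen_rmats


def make_event(
    event_id="e1",
    chrom="chr1",
    strand="+",
    left=(100, 200),
    alt=(300, 400),
    right=(500, 600),
    ijc_g1=(20, 20),
    sjc_g1=(5, 5),
    ijc_g2=(20, 20),
    sjc_g2=(5, 5),
    p=0.5,
    fdr=0.5,
    dpsi=0.0,
):
    return ASEvent(
        event_id=event_id,
        gene_id=f"GENE_{event_id}",
        gene_symbol=f"G_{event_id}",
        chrom=chrom,
        strand=strand,
        alt_exon_start=alt[0],
        alt_exon_end=alt[1],
        left_flank_start=left[0],
        left_flank_end=left[1],
        right_flank_start=right[0],
        right_flank_end=right[1],
        ijc_g1=ijc_g1,
        sjc_g1=sjc_g1,
        ijc_g2=ijc_g2,
        sjc_g2=sjc_g2,
        inc_form_len=198,
        skip_form_len=99,
        p_value=p,
        fdr=fdr,
        inc_level_g1=(0.5, 0.5),
        inc_level_g2=(0.5, 0.5),
        inc_level_difference=dpsi,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded synthetic rMATS dataset shared across read-only tests."""
    spec = SimSpec(seed=11, n_events=300)
    events, truth = gen_rmats(spec)
    return spec, events, truth
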