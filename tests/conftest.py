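import pytest

from meprod.design import ChannelSpec, PlexDesign
from meprod.io import make_record


@pytest.fixture
def design6() -> PlexDesign:
    """Hand-built 6-plex: noise, 2x2 samples (control/treated), booster at 200%."""
    return PlexDesign(
        plex_id="toy",
        channels=(
            ChannelSpec(channel_id="126", role="noise"),
            ChannelSpec(channel_id="127N", role="sample", condition="control", replicate=1),
            ChannelSpec(channel_id="127C", role="sample", condition="control", replicate=2),
            ChannelSpec(channel_id="128N", role="sample", condition="treated", replicate=1),
            ChannelSpec(channel_id="128C", role="sample", condition="treated", replicate=2),
            ChannelSpec(channel_id="129N", role="booster", booster_molar_ratio=2.0),
        ),
    )


def record(design, sequence, accession, values, heavy=True, sn=None, mods=None):
    """Shorthand for building a PeptideRecord against a design's channels."""
    if mods is None:
        mods = "TMT6(N-Term); TMT6+K8(K8)" if heavy else "TMT6(N-Term)"
    return make_record(
        sequence=sequence,
        modifications=mods,
        master_accession=accession,
        intensities=dict(zip(design.channel_ids, values)),
        sn=sn,
    )


@pytest.fixture
def make_toy_record():
    return record
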