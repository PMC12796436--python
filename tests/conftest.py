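import pytest

from soilfoodweb import Config
from soilfoodweb.model import Guild, SiteBundle, SiteContext
from soilfoodweb.synthetic import generate_fixture_web, generate_site


@pytest.fixture
def config():
    return Config()


@pytest.fixture
def chain3():
    return generate_fixture_web("chain3")


@pytest.fixture
def loop_web():
    return generate_fixture_web("loop")


@pytest.fixture
def star_web():
    return generate_fixture_web("star")


@pytest.fixture
def taiga_site():
    return generate_site("taiga", 3)


def make_guild(gid, biomass=1.0, mass=1.0, prefs=None, habitat=None, **kw):
    """Minimal guild constructor for hand-built webs."""
    return Guild(
        guild_id=gid,
        taxon_group=gid,
        layer_biomass={"litter": biomass},
        mean_body_mass=mass,
        preferences=prefs or {"L": 1.0},
        habitat=habitat or {"litter": 1.0},
        **kw,
    )


def make_bundle(guilds, forest_type="beech", temperature=7.5, **kw):
    return SiteBundle(
        context=SiteContext(
            site_id="test", forest_type=forest_type,
            mean_annual_temperature=temperature, **kw,
        ),
        guilds=guilds,
    )
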