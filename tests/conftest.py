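import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mibci.montage import default_montage, epoch_trials
from mibci.synth import SyntheticConfig, generate_recording

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def tiny_config():
    """One subject, four trials per state: enough to exercise every stage."""
    return SyntheticConfig(n_subjects=1, trials_per_state=4, train_per_state=3, seed=3)


@pytest.fixture(scope="session")
def tiny_recording(tiny_config):
    return generate_recording(tiny_config, 0)


@pytest.fixture(scope="session")
def raw_trials(tiny_recording):
    """Raw (unfiltered) 5 s motor-imagery epochs with blink contamination."""
    return epoch_trials(tiny_recording, (2.0, 7.0))


def write_minimal_edf(path, data_uv, ch_names, fs):
    """Hand-rolled single-spec EDF writer for test fixtures (1 s records,
    16-bit, physical range +/-3000 uV). Generated at test time; never stored."""
    n_ch = len(ch_names)
    n_records = int(round(data_uv.shape[1] / fs))
    spr = int(fs)
    phys_min, phys_max = -3000.0, 3000.0
    dig_min, dig_max = -32768, 32767

    def field(vals, width):
        return b"".join(str(v).encode()[:width].ljust(width) for v in vals)

    hdr = b"0".ljust(8) + b"X".ljust(80) + b"X".ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 * (n_ch + 1)).encode().ljust(8) + b" ".ljust(44)
    hdr += str(n_records).encode().ljust(8) + b"1".ljust(8)
    hdr += str(n_ch).encode().ljust(4)
    hdr += field(ch_names, 16) + field([""] * n_ch, 80) + field(["uV"] * n_ch, 8)
    hdr += field([phys_min] * n_ch, 8) + field([phys_max] * n_ch, 8)
    hdr += field([dig_min] * n_ch, 8) + field([dig_max] * n_ch, 8)
    hdr += field([""] * n_ch, 80) + field([spr] * n_ch, 8) + field([""] * n_ch, 32)
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    dig = np.clip(
        np.round((data_uv - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            for c in range(n_ch):
                fh.write(dig[c, r * spr : (r + 1) * spr].tobytes())
    return path


@pytest.fixture
def edf_writer():
    return write_minimal_edf
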