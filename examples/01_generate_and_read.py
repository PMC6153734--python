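"""Generate a synthetic EGG recording, write it to ASCII, and read it back.

The file carries an 8-row header (meal times, sampling frequency, A/D
scale) and space-separated integer counts from line 9.
"""

import tempfile
from pathlib import Path

from eggkit import SyntheticSpec, gen_egg, read_egg_ascii

path = Path(tempfile.mkdtemp()) / "synthetic_3cpm.txt"
spec = SyntheticSpec(freq_cpm=3.0, snr_db=10.0, duration_min=10.0, seed=1)
rec = gen_egg(spec, path=path)

back = read_egg_ascii(path)
print(f"wrote {path} ({path.stat().st_size/1e6:.1f} MB)")
print(f"fs = {back.meta.fs_hz} Hz, scale 1 mV = {back.meta.counts_per_mv:g} counts")
print(f"channels: {back.channels}, {back.n_samples} samples "
      f"({back.duration_s/60:.0f} min)")
print(f"peak amplitude: {abs(back.data).max()*1000:.0f} uV "
      "(a gastric slow wave is typically 50-400 uV)")
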