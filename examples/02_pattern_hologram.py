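"""Decode a letter pattern into array drives and verify by forward simulation.

A letter-"C" intensity mask (4 mm side) at 10 mm depth is backpropagated to
the 16×16 array plane (band-limited angular spectrum), averaged over the
element apertures, and the resulting per-element amplitudes/phases are
propagated forward again to check the delivered pattern.
"""

import numpy as np

from sonoretina import TargetPattern, decode_pattern, synthesize_field
from sonoretina.pipeline import letter_c_pattern

target = TargetPattern(letter_c_pattern(), Li=4.0, z=10.0)
drive = decode_pattern(target)
print(f"decoded {drive.amplitude.size} element drives; "
      f"amplitude range [{drive.amplitude.min():.3f}, {drive.amplitude.max():.3f}]")

field = synthesize_field(drive, z=10.0)
mag = field.magnitude
g = field.grid
inside = mag[np.ix_(np.abs(g.y) <= 2.0, np.abs(g.x) <= 2.0)]
print(f"delivered field at z = 10 mm: peak |p| = {mag.max():.3f} (relative), "
      f"{(inside > 0.5 * mag.max()).mean():.1%} of the 4×4 mm window above half max")
print("The bright region traces the commanded 'C'; its edge sharpness is set")
print("by the aperture's diffraction limit (~0.3 mm at 4.5 MHz, z = 10 mm).")
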