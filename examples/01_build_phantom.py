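"""Build a digital AAA phantom and inspect its analytic ground truth.

The phantom is a straight aorta with a fusiform bulge, intraluminal
thrombus (ILT) and a 2 mm wall, plus psoas muscle and spine reference
structures, rasterised at 1.3 mm isotropic resolution.
"""

from aortacs import build_phantom, default_spec

spec = default_spec(max_diameter_cm=4.5, ilt_type=2, seed=0)
phantom = build_phantom(spec)

t = phantom.truth
print(f"grid {phantom.intensity.shape}, voxel {phantom.voxel_size} mm")
print(f"max outer diameter : {t.max_outer_diameter:.2f} cm (slice {t.slice_of_max})")
print(f"lumen area         : {t.lumen_area_at_max:.2f} cm^2 at the widest slice")
print(f"ILT+wall area      : {t.ilt_wall_area_at_max:.2f} cm^2")
print(f"ILT/muscle ratio   : {t.ilt_muscle_ratio:.2f}  (type {t.ilt_type} thrombus)")
# These values come from the continuous geometry, not from the raster: they
# are the reference against which every image-based measurement is judged.
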