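"""Build synthetic layered head geometry and OPM sensor arrays.

Creates the nested white/pial/mid cortical surfaces plus a scalp sphere,
packs magnetometers on the scalp at several inter-sensor distances, attaches
one to three measurement axes, and moves the array to an on-scalp (6.5 mm)
or off-scalp offset.  Printed counts show how sensor density and axis count
set the channel budget of an array design.
"""

import numpy as np

import opmlaminar as om

space, scalp = om.make_head_geometry(subdivisions=3, bump_amplitude_mm=2.0, seed=0)
sep = np.linalg.norm(space.pial.vertices - space.white.vertices, axis=1)
print(f"cortical layers: {space.white.n_vertices} vertices each, "
      f"separation {sep.mean():.2f} mm")

for spacing in (55.0, 45.0, 35.0, 25.0):
    arr = om.pack_sensors(scalp, spacing, seed=1)
    print(f"  {spacing:4.0f} mm inter-sensor distance -> {arr.n_sensors:3d} sensors", end="")
    for n_axes in (1, 2, 3):
        print(f"  |  {n_axes} axis: {om.build_channel_axes(arr, n_axes).n_channels:3d} ch", end="")
    print()

arr = om.build_channel_axes(om.pack_sensors(scalp, 45.0, seed=1), 3)
on_scalp = om.offset_sensors(arr, scalp, 6.5)
off_scalp = om.offset_sensors(arr, scalp, 30.0)
print(f"on-scalp offset {on_scalp.offset_mm} mm, sensor radius "
      f"{np.linalg.norm(on_scalp.positions, axis=1).mean():.1f} mm; "
      f"off-scalp {off_scalp.offset_mm} mm -> "
      f"{np.linalg.norm(off_scalp.positions, axis=1).mean():.1f} mm")

# co-registration error: displaced fiducials induce a rigid mis-alignment
pert, tf = om.perturb_fiducials(on_scalp, sd_mm=2.0, seed=3)
shift = np.linalg.norm(pert.positions - on_scalp.positions, axis=1)
print(f"2 mm fiducial error -> sensors displaced {shift.mean():.2f} mm on average "
      f"(rigid transform, det R = {np.linalg.det(tf.rotation):.6f})")
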