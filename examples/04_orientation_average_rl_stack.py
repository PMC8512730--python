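"""Orientation averaging: chiral vs achiral fibers tumbling in water.

A single-handed turn keeps a non-zero CIDS after averaging over particle
orientations, but stacking one right-handed and one left-handed turn (an
exactly mirror-symmetric, achiral composite) cancels the averaged CIDS to
numerical zero -- CIDS reads out the average handedness.
"""

import numpy as np

import chiroscat as cs

spec = cs.SolenoidSpec()
theta = np.arange(0.0, 181.0, 2.0)
quad = cs.make_quadrature(4, 4, 2)  # 32 Euler-angle nodes

single = cs.voxelize(cs.nucleosome_poses(spec), spec.shape, 16)
avg_single, cross_single = cs.orientation_average(single, quadrature=quad, theta_deg=theta, tol=1e-6)

stack = cs.voxelize(cs.composite_poses(cs.stack_opposite_handed(spec)), spec.shape, 16)
avg_stack, cross_stack = cs.orientation_average(stack, quadrature=quad, theta_deg=theta, tol=1e-6)
fixed_stack = cs.scattering_run(stack, theta_deg=np.arange(0.0, 360.0, 1.0), tol=1e-8)

print(f"single-handed turn  (N={single.n_dipoles}): "
      f"<max|CIDS|> = {cs.cids_from_mueller(avg_single).max_abs:.3e}  Q_ext = {cross_single.Q_ext:.4g}")
print(f"R+L two-turn stack  (N={stack.n_dipoles}): "
      f"<max|CIDS|> = {cs.cids_from_mueller(avg_stack).max_abs:.3e}  Q_ext = {cross_stack.Q_ext:.4g}")
print(f"R+L stack, fixed orientation: max|CIDS| = "
      f"{cs.cids_from_mueller(fixed_stack.mueller).max_abs:.3e}")
print("\nThe averaged stack signal is numerically zero (achiral composite);")
print("the fixed-orientation stack and the averaged single-handed fiber are not.")
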