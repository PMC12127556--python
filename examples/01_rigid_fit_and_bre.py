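"""Fit a rigid transform to deformed points and read off the BRE.

Takes a small point cloud, deforms it with a known rotation + translation
plus isotropic scaling about the centroid, fits the least-squares rigid
transform and prints the mean residual — the bone rigidity error.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from breqa import CorrespondenceSet, compute_bre, fit_rigid

rng = np.random.default_rng(0)
X = rng.normal(size=(200, 3)) * 15.0  # fixed-image points, mm

R_true = Rotation.from_rotvec([0.0, 0.0, np.deg2rad(10)]).as_matrix()
t_true = np.array([4.0, -2.0, 1.0])
s = 1.05  # 5 % isotropic expansion about the centroid: a rigidity violation

c = X.mean(axis=0)
Y = (c + s * (X - c)) @ R_true.T + t_true

corr = CorrespondenceSet(X=X, Y=Y)
tf = fit_rigid(corr)
bre = compute_bre(corr, tf)

angle = np.rad2deg(Rotation.from_matrix(tf.R).magnitude())
expected = abs(s - 1) * np.mean(np.linalg.norm(X - c, axis=1))
print(f"fitted rotation angle : {angle:.3f} deg (generated with 10 deg)")
print(f"BRE                   : {bre:.4f} mm")
print(f"closed form |s-1|*E|x-c| : {expected:.4f} mm")
print(
    "The fit absorbs the rigid part exactly; what remains is the scaling\n"
    "violation, so the BRE equals the closed-form residual of a 5 % expansion."
)
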