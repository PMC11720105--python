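"""Rotation conventions, SO(3) projection and the two evaluation metrics.

Shows the package's Euler convention (roll about anterior +x, pitch about
left +y, yaw about superior +z), the SVD projection that turns a raw network
output into a proper rotation, and the geodesic rotation error (RE).
"""

import numpy as np

from nhpnet import EulerAngles, euler_to_matrix, matrix_to_euler, project_to_so3, rotation_error

e = EulerAngles(roll=3.0, pitch=-4.0, yaw=5.0)
R = euler_to_matrix(e)
print("rotation for (3, -4, 5) deg:\n", R.round(4))
print("recovered angles:", matrix_to_euler(R))

raw = R + 0.15 * np.random.default_rng(0).standard_normal((3, 3))  # noisy 9-element output
R_hat = project_to_so3(raw)
print("\nraw output determinant:", round(float(np.linalg.det(raw)), 4))
print("projected determinant:  ", round(float(np.linalg.det(R_hat)), 4))
print(f"RE(projected, truth) = {rotation_error(R_hat, R):.3f} deg")
print(f"RE(identity,  truth) = {rotation_error(np.eye(3), R):.3f} deg")
print("(RE is the geodesic angle arccos((Tr(R_hat R^T) - 1)/2), in degrees)")
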