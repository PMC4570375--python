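"""Weighted-covariance ellipse fitting of a fly blob.

Renders one anisotropic Gaussian fly profile with known pose and recovers
its centre, half-axes and orientation from the pixel weights.
"""

import math

import numpy as np

import flytrack as ft

x0, y0, theta = 40.0, 38.5, math.radians(30)
sa, sb = 6.0, 2.5  # profile sd; the fitted half-axes are 2*sd

yy, xx = np.mgrid[0:80, 0:80]
ct, st = math.cos(theta), math.sin(theta)
u = ct * (xx - x0) + st * (yy - y0)
v = -st * (xx - x0) + ct * (yy - y0)
depth = 120.0 * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))
rows, cols = np.nonzero(depth > 1.0)

e = ft.fit_ellipse(np.column_stack([cols, rows]), depth[rows, cols])
print(f"true pose:  centre=({x0:.1f}, {y0:.1f})  a={2*sa:.1f}  b={2*sb:.1f}  "
      f"theta={math.degrees(theta):.1f} deg")
print(f"recovered:  centre=({e.x:.1f}, {e.y:.1f})  a={e.a:.1f}  b={e.b:.1f}  "
      f"theta={math.degrees(e.theta):.1f} deg")
# The centre is the weight-averaged position, the half-axes are twice the
# square roots of the weighted-covariance eigenvalues, and the orientation
# (an axis, defined modulo 180 deg) follows the leading eigenvector.
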