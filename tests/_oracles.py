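"""Independent numerical oracles shared across test modules."""

import numpy as np

PROBE = 1.4


def grid_sasa(coords, radii, probe=PROBE, n_theta=180, n_phi=360):
    """Independent dense latitude-longitude quadrature oracle (no periodicity)."""
    total = np.zeros(len(coords))
    theta_edges = np.linspace(0, np.pi, n_theta + 1)
    theta = 0.5 * (theta_edges[:-1] + theta_edges[1:])
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    # exact band areas so the quadrature integrates the sphere exactly
    band_area = np.cos(theta_edges[:-1]) - np.cos(theta_edges[1:])
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    weights = np.repeat(band_area / n_phi, n_phi)
    inflated = radii + probe
    for i in range(len(coords)):
        pts = coords[i] + inflated[i] * dirs
        free = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= ((pts - coords[j]) ** 2).sum(axis=1) >= inflated[j] ** 2
        total[i] = (weights * free).sum() * 2 * np.pi * inflated[i] ** 2
    return total
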