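import numpy as np
import pytest

from sulcalpits import TriangleMesh, make_sheet, make_sphere


@pytest.fixture(scope="session")
def unit_triangle():
    return TriangleMesh(
        vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]),
        faces=np.array([[0, 1, 2]]),
    )


@pytest.fixture(scope="session")
def small_sphere():
    """162-vertex unit icosphere."""
    return make_sphere(subdivisions=2, radius=1.0)


@pytest.fixture(scope="session")
def brain_sphere():
    """642-vertex sphere at cortical scale (r = 50 mm)."""
    return make_sphere(subdivisions=3, radius=50.0)


@pytest.fixture(scope="session")
def sheet():
    """41 x 41 flat grid, 2 mm spacing (80 mm square)."""
    return make_sheet(n=41, spacing=2.0)


def cylinder_mesh(length=100.0, radius=5.0, n_axial=40, n_circ=12, wobble=0.0):
    """Open tube along z (no caps): connected, manifold, orientable.

    `wobble` adds a deterministic radial perturbation that breaks the
    rotational symmetry (needed when Fiedler extrema must be unique)."""
    zs = np.linspace(0.0, length, n_axial)
    thetas = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    verts = np.array(
        [
            [
                radius * (1 + wobble * np.sin(3 * t + 0.37 * z)) * np.cos(t),
                radius * (1 + wobble * np.sin(3 * t + 0.37 * z)) * np.sin(t),
                z,
            ]
            for z in zs
            for t in thetas
        ]
    )
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = a + n_circ
            d = b + n_circ
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriangleMesh(verts, np.asarray(faces))


def permute_mesh(mesh, rng):
    """Relabel vertices by a random permutation; returns (mesh, perm) with
    new_index = perm[old_index]."""
    n = mesh.n_vertices
    perm = rng.permutation(n)
    inv = np.empty(n, dtype=np.int64)
    inv[perm] = np.arange(n)
    verts = mesh.vertices[inv]
    faces = perm[mesh.faces]
    return TriangleMesh(verts, faces, mesh.hemisphere), perm


def rigid_motion(mesh, rng):
    """Apply a random rotation + translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(size=3) * 10
    return TriangleMesh(mesh.vertices @ Q.T + t, mesh.faces.copy(), mesh.hemisphere)


def bumpy_mesh(seed, subdivisions=2, radius=20.0):
    """Random radially-perturbed sphere for oracle cross-checks."""
    rng = np.random.default_rng(seed)
    base = make_sphere(subdivisions=subdivisions, radius=radius)
    r = 1.0 + 0.08 * rng.standard_normal(base.n_vertices)
    return TriangleMesh(base.vertices * r[:, None], base.faces.copy())


def blob_depth_field(mesh, seed, n_blobs=4, amp=5.0):
    """Smooth random depth field: sum of Gaussian bumps + low noise."""
    from sulcalpits.mesh import geodesic_distance

    rng = np.random.default_rng(seed)
    centers = rng.choice(mesh.n_vertices, size=n_blobs, replace=False)
    depth = 0.02 * rng.standard_normal(mesh.n_vertices)
    for c in centers:
        g = geodesic_distance(mesh, [int(c)])
        depth += rng.uniform(0.5, 1.0) * amp * np.exp(-(g**2) / (2 * 36.0))
    return depth
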