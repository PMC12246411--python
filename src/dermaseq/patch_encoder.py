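"""Patch-wise sequence encoding of an image.

An (H, W, C) image is cut into N = H*W/P^2 non-overlapping P x P
patches in row-major grid order; each patch is flattened channel-last
to a vector x_i of length P^2*C and linearly embedded, z_i = E @ x_i.
Optionally a learned classification token z_CLS is prepended and a
positional embedding matrix E_pos is added elementwise:

    Z_0 = [z_CLS; z_1; ...; z_N] + E_pos

The embedded sequence is the token stream consumed by the hybrid
classifier's recurrent stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchSequence",
    "EmbeddingConfig",
    "EmbeddedSequence",
    "extract_patches",
    "reassemble_patches",
    "make_embedding_params",
    "embed_sequence",
]


@dataclass
class PatchSequence:
    """Ordered flattened patches of one image (row-major patch grid)."""

    patches: np.ndarray    # (N, P*P*C)
    patch_size: int
    image_shape: tuple     # (H, W, C)


@dataclass(frozen=True)
class EmbeddingConfig:
    patch_size_P: int = 10
    embed_dim_D: int = 64
    include_cls: bool = False
    init_seed: int = 0

    def validate(self) -> None:
        if self.embed_dim_D < 1:
            raise ValueError(f"embed_dim_D must be >= 1, got {self.embed_dim_D}")
        if self.patch_size_P < 1:
            raise ValueError(f"patch_size_P must be >= 1, got {self.patch_size_P}")


@dataclass
class EmbeddedSequence:
    tokens: np.ndarray       # (N or N+1, D)
    positions_added: bool
    has_cls: bool


def extract_patches(image: np.ndarray, P: int) -> PatchSequence:
    """Cut an image into N = H*W/P^2 flattened patches, row-major.

    P must divide both H and W exactly; non-divisible sizes are a hard
    error (silent padding would corrupt downstream ground truth).
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[:, :, None]
    h, w, c = image.shape
    if h % P or w % P:
        raise ValueError(
            f"patch size P={P} must divide image dimensions H={h}, W={w}")
    gh, gw = h // P, w // P
    patches = (image.reshape(gh, P, gw, P, c)
                    .transpose(0, 2, 1, 3, 4)
                    .reshape(gh * gw, P * P * c))
    return PatchSequence(patches=patches, patch_size=P, image_shape=(h, w, c))


def reassemble_patches(seq: PatchSequence, H: int, W: int) -> np.ndarray:
    """Exact inverse of :func:`extract_patches`."""
    P = seq.patch_size
    n, flat = seq.patches.shape
    c = flat // (P * P)
    if flat != P * P * c or n * P * P != H * W:
        raise ValueError(
            f"inconsistent dimensions: N={n}, P={P}, H={H}, W={W}")
    gh, gw = H // P, W // P
    img = (seq.patches.reshape(gh, gw, P, P, c)
                      .transpose(0, 2, 1, 3, 4)
                      .reshape(H, W, c))
    return img


def make_embedding_params(cfg: EmbeddingConfig, input_dim: int,
                          n_tokens: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded initial (E, E_pos, z_cls) for an embedding configuration.

    All entries uniform in [-1/sqrt(D), +1/sqrt(D)] — a scale-stable
    init reproducible from ``cfg.init_seed``.  E has shape (D, input_dim)
    so that z_i = E @ x_i; E_pos has one row per token (including the
    CLS slot when enabled).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.init_seed)
    d = cfg.embed_dim_D
    lim = 1.0 / np.sqrt(d)
    n_rows = n_tokens + (1 if cfg.include_cls else 0)
    E = rng.uniform(-lim, lim, size=(d, input_dim))
    E_pos = rng.uniform(-lim, lim, size=(n_rows, d))
    z_cls = rng.uniform(-lim, lim, size=d)
    return E, E_pos, z_cls


def embed_sequence(seq: PatchSequence, cfg: EmbeddingConfig,
                   E: np.ndarray, E_pos: np.ndarray | None = None,
                   z_cls: np.ndarray | None = None) -> EmbeddedSequence:
    """Linearly embed a patch sequence and add positional terms.

    Token i is E @ x_i; when ``cfg.include_cls`` the z_CLS vector is
    prepended at index 0; E_pos (one row per token) is added elementwise
    after concatenation.
    """
    cfg.validate()
    x = seq.patches.astype(float)
    d, in_dim = E.shape
    if d != cfg.embed_dim_D:
        raise ValueError(f"E has {d} rows, expected embed_dim_D={cfg.embed_dim_D}")
    if in_dim != x.shape[1]:
        raise ValueError(
            f"E maps vectors of length {in_dim}, patches have length {x.shape[1]}")
    z = x @ E.T                               # (N, D)
    if cfg.include_cls:
        if z_cls is None:
            raise ValueError("include_cls requires a z_cls vector")
        if z_cls.shape != (d,):
            raise ValueError(f"z_cls must have shape ({d},), got {z_cls.shape}")
        z = np.vstack([z_cls[None, :], z])
    positions_added = False
    if E_pos is not None:
        if E_pos.shape != z.shape:
            raise ValueError(
                f"E_pos shape {E_pos.shape} must match token array {z.shape}")
        z = z + E_pos
        positions_added = True
    return EmbeddedSequence(tokens=z, positions_added=positions_added,
                            has_cls=cfg.include_cls)
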