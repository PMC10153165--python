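"""ENVI: environmental variational inference.

A conditional variational autoencoder that places spatial transcriptomics
cells (partial gene panel, with spatial context) and dissociated scRNA-seq
cells (full transcriptome, no context) in one latent space. A binary
auxiliary neuron ``c`` (0 = spatial, 1 = single-cell) appended to the
encoder and expression-decoder inputs marginalizes technology effects.

Three networks:

* a shared encoder mapping panel expression + ``c`` to a diagonal Gaussian
  posterior (mu, sigma) over the latent;
* an *expression* decoder producing count-distribution parameters — the
  full transcriptome under the single-cell family (negative binomial by
  default) when ``c = 1``, the imaged panel under the spatial family
  (Poisson by default) when ``c = 0``. Only the first ``g_st`` rate units
  of the output layer are shared between modalities; the remaining units
  train exclusively on single-cell data, absorbing technology-specific
  effects beyond the auxiliary neuron;
* an *environment* decoder whose g_cov(g_cov+1)/2 outputs fill the lower
  triangle of a Cholesky factor L; the Gramian L L^T is the mean of an
  identity-covariance Gaussian over the cell's COVET matrix square root, so
  its log-likelihood is (up to constants) the squared AOT distance.

Training maximizes the evidence lower bound with a standard-normal prior:
count log-likelihoods for both modalities, the environment Gaussian term
for the spatial half, minus beta times the KL divergence of the posterior.
COVET MSQR targets are precomputed once for all spatial cells before any
gradient step. After training, unmeasured genes are imputed for spatial
cells by decoding their latent with the single-cell flag, and niches are
inferred for dissociated cells by applying the environment decoder to
their latent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import distributions as dist
from .autodiff import Adam, Parameter, Tensor, concat
from .covet import covet_from_dataset, highly_variable_panel_genes
from .data import SingleCellDataset, SpatialDataset, match_panel


@dataclass
class EnviConfig:
    """Hyperparameters; defaults follow the published training recipe."""

    latent_dim: int = 512
    hidden_layers: tuple = (1024, 1024, 1024)
    beta: float = 0.3  # prior (KL) coefficient
    steps: int = 2**14
    batch_size: int = 1024  # split half/half by modality
    learning_rate: float = 1e-4
    final_quarter_lr: float | None = None  # optional drop, e.g. 1e-5
    spatial_family: str = "poisson"
    sc_family: str = "negative_binomial"
    covet_k: int = 8
    covet_genes: int = 64  # spatial-panel HVGs used for COVET
    covet_transform: str = "raw"
    hvg_union: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.batch_size % 2:
            raise ValueError("batch_size must be even (half per modality)")
        for fam in (self.spatial_family, self.sc_family):
            if fam not in dist.FAMILIES:
                raise ValueError(f"unknown family {fam!r}")


@dataclass
class LatentPosterior:
    mu: np.ndarray
    sigma: np.ndarray


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class _Linear:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = Parameter(_glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class _MLP:
    """ReLU multilayer perceptron trunk."""

    def __init__(self, rng, n_in: int, hidden: tuple):
        self.layers = []
        prev = n_in
        for h in hidden:
            self.layers.append(_Linear(rng, prev, h))
            prev = h
        self.n_out = prev

    def __call__(self, x: Tensor) -> Tensor:
        for lin in self.layers:
            x = lin(x).relu()
        return x

    @property
    def params(self):
        return [p for lin in self.layers for p in lin.params]


class EnviModel:
    """Encoder + expression/environment decoders with the modality convention
    c=0 for spatial and c=1 for single-cell data."""

    def __init__(self, g_st: int, g_sc: int, g_cov: int, config: EnviConfig):
        if g_st > g_sc:
            raise ValueError("the spatial panel cannot exceed the single-cell gene set")
        self.g_st, self.g_sc, self.g_cov = g_st, g_sc, g_cov
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden_layers
        d = config.latent_dim

        # encoder: panel expression + auxiliary neuron
        self.enc_trunk = _MLP(rng, g_st + 1, h)
        self.enc_mu = _Linear(rng, self.enc_trunk.n_out, d)
        self.enc_sigma = _Linear(rng, self.enc_trunk.n_out, d)

        # expression decoder: latent + auxiliary neuron; rate output layer is
        # split into shared (first g_st units) and single-cell-only units
        self.dec_trunk = _MLP(rng, d + 1, h)
        self.dec_rate_shared = _Linear(rng, self.dec_trunk.n_out, g_st)
        self.dec_rate_sc_only = _Linear(rng, self.dec_trunk.n_out, g_sc - g_st)
        # per-gene auxiliary parameters (success probability / dropout / scale)
        self.sc_p_logit = Parameter(np.zeros(g_sc))
        self.sc_dropout_logit = Parameter(np.full(g_sc, -2.0))
        self.sc_log_scale = Parameter(np.zeros(g_sc))
        self.st_p_logit = Parameter(np.zeros(g_st))
        self.st_dropout_logit = Parameter(np.full(g_st, -2.0))
        self.st_log_scale = Parameter(np.zeros(g_st))

        # environment decoder: latent only (no auxiliary neuron)
        self.env_trunk = _MLP(rng, d, h)
        self.env_out = _Linear(rng, self.env_trunk.n_out, g_cov * (g_cov + 1) // 2)
        self._tril_idx = np.tril_indices(g_cov)

        self.trained = False
        self.loss_history: list[dict] = []
        # populated by train(): gene bookkeeping for imputation outputs
        self.sc_gene_names: np.ndarray | None = None
        self.covet_gene_names: np.ndarray | None = None

    # -- parameter groups --------------------------------------------------

    @property
    def parameters(self):
        return (
            self.enc_trunk.params + self.enc_mu.params + self.enc_sigma.params
            + self.dec_trunk.params + self.dec_rate_shared.params
            + self.dec_rate_sc_only.params
            + [self.sc_p_logit, self.sc_dropout_logit, self.sc_log_scale,
               self.st_p_logit, self.st_dropout_logit, self.st_log_scale]
            + self.env_trunk.params + self.env_out.params
        )

    # -- forward pieces ----------------------------------------------------

    @staticmethod
    def _with_flag(x: np.ndarray, c: float) -> np.ndarray:
        flag = np.full((x.shape[0], 1), float(c))
        return np.concatenate([x, flag], axis=1)

    @staticmethod
    def _encoder_input(expr: np.ndarray) -> np.ndarray:
        # log-transform stabilizes the plain MLP on raw counts
        return np.log1p(np.asarray(expr, dtype=np.float64))

    def encode_t(self, expr: np.ndarray, c: float):
        if expr.shape[1] != self.g_st:
            raise ValueError(
                f"encoder expects {self.g_st} panel genes, got {expr.shape[1]}"
            )
        x = Tensor(self._with_flag(self._encoder_input(expr), c))
        hdn = self.enc_trunk(x)
        mu = self.enc_mu(hdn)
        sigma = self.enc_sigma(hdn).softplus() + 1e-6
        return mu, sigma

    def encode(self, expr: np.ndarray, c: float) -> LatentPosterior:
        mu, sigma = self.encode_t(expr, c)
        return LatentPosterior(mu=mu.data.copy(), sigma=sigma.data.copy())

    @staticmethod
    def sample_latent(post: LatentPosterior, eps: np.ndarray) -> np.ndarray:
        """Reparameterization: l = mu + eps * sigma."""
        return post.mu + eps * post.sigma

    def _aux_params(self, modality: str, n_genes: int):
        if modality == "sc":
            return self.sc_p_logit, self.sc_dropout_logit, self.sc_log_scale
        return self.st_p_logit, self.st_dropout_logit, self.st_log_scale

    def decode_expression_t(self, l, c: float) -> dict:
        if not isinstance(l, Tensor):
            l = Tensor(np.asarray(l, dtype=np.float64))
        flag = np.full((l.shape[0], 1), float(c))
        hdn = self.dec_trunk(concat([l, Tensor(flag)], axis=1))
        family = self.config.sc_family if c == 1 else self.config.spatial_family
        if c == 1:
            rate = concat(
                [self.dec_rate_shared(hdn), self.dec_rate_sc_only(hdn)], axis=1
            ).softplus() + 1e-6
            p_logit, drop_logit, log_scale = self._aux_params("sc", self.g_sc)
        else:
            rate = self.dec_rate_shared(hdn).softplus() + 1e-6
            p_logit, drop_logit, log_scale = self._aux_params("st", self.g_st)
        params: dict = {"family": family}
        if family == "poisson":
            params["lam"] = rate
        elif family in ("negative_binomial", "zinb"):
            params["r"] = rate
            params["p"] = dist.clamp_probability(p_logit.sigmoid())
            if family == "zinb":
                params["dropout"] = drop_logit.sigmoid()
        elif family == "normal":
            params["mu"] = rate
            params["scale"] = log_scale.exp()
        return params

    def decode_expression(self, l: np.ndarray, c: float) -> dict:
        params = self.decode_expression_t(l, c)
        return {
            k: (v.data.copy() if isinstance(v, Tensor) else v)
            for k, v in params.items()
        }

    def decode_environment_t(self, l) -> Tensor:
        """Predicted COVET MSQR: Gramian L L^T of the Cholesky-factor output."""
        if not isinstance(l, Tensor):
            l = Tensor(np.asarray(l, dtype=np.float64))
        tri = self.env_out(self.env_trunk(l))  # (b, g(g+1)/2)
        L = _fill_tril(tri, self.g_cov, self._tril_idx)
        return _batch_gramian(L)

    def decode_environment(self, l: np.ndarray) -> np.ndarray:
        return self.decode_environment_t(l).data.copy()

    # -- loss ---------------------------------------------------------------

    def elbo_loss(
        self,
        st_expr: np.ndarray,
        st_msqr: np.ndarray,
        sc_expr_panel: np.ndarray,
        sc_expr_full: np.ndarray,
        rng: np.random.Generator,
    ):
        """Negative ELBO on a mixed batch; returns (loss Tensor, components)."""
        mu_st, sig_st = self.encode_t(st_expr, c=0.0)
        mu_sc, sig_sc = self.encode_t(sc_expr_panel, c=1.0)
        eps_st = rng.standard_normal(mu_st.shape)
        eps_sc = rng.standard_normal(mu_sc.shape)
        l_st = mu_st + sig_st * eps_st
        l_sc = mu_sc + sig_sc * eps_sc

        st_params = self.decode_expression_t(l_st, c=0.0)
        sc_params = self.decode_expression_t(l_sc, c=1.0)
        st_ll = dist.log_prob(st_params["family"], st_params, st_expr).sum(axis=1).mean()
        sc_ll = dist.log_prob(sc_params["family"], sc_params, sc_expr_full).sum(axis=1).mean()

        msqr_pred = self.decode_environment_t(l_st)
        diff = msqr_pred - st_msqr
        g2 = self.g_cov * self.g_cov
        env_ll = (
            -(diff * diff).reshape(diff.shape[0], g2).sum(axis=1) * 0.5
            - 0.5 * g2 * np.log(2.0 * np.pi)
        ).mean()

        kl_st = dist.kl_diag_gaussian(mu_st, sig_st)
        kl_sc = dist.kl_diag_gaussian(mu_sc, sig_sc)
        kl = (kl_st.mean() + kl_sc.mean()) * 0.5

        loss = -(st_ll + sc_ll + env_ll) + self.config.beta * kl
        comps = {
            "spatial_ll": float(st_ll.data),
            "sc_ll": float(sc_ll.data),
            "env_ll": float(env_ll.data),
            "kl": float(kl.data),
            "loss": float(loss.data),
        }
        for name, v in comps.items():
            if not np.isfinite(v):
                raise FloatingPointError(f"non-finite ELBO component {name!r}")
        return loss, comps

    # -- inference ----------------------------------------------------------

    def _require_trained(self) -> None:
        if not self.trained:
            raise RuntimeError("model has not been trained")

    def impute_genes(self, spatial_expr: np.ndarray, sample: bool = False,
                     rng: np.random.Generator | None = None) -> np.ndarray:
        """Expected full-transcriptome counts for spatial cells.

        Encodes with the spatial flag, decodes with the single-cell flag
        under the single-cell family, and returns the distribution mean.
        Uses the posterior mean by default (deterministic); ``sample=True``
        draws one latent sample instead.
        """
        self._require_trained()
        post = self.encode(spatial_expr, c=0.0)
        latent = post.mu
        if sample:
            rng = rng or np.random.default_rng(self.config.seed)
            latent = self.sample_latent(post, rng.standard_normal(post.mu.shape))
        params = self.decode_expression(latent, c=1.0)
        return dist.family_mean(params["family"], params)

    def infer_covet(self, sc_expr_panel: np.ndarray) -> np.ndarray:
        """Predicted COVET MSQRs for dissociated cells, (n_sc, g_cov, g_cov)."""
        self._require_trained()
        post = self.encode(sc_expr_panel, c=1.0)
        return self.decode_environment(post.mu)

    def latent_means(self, expr_panel: np.ndarray, c: float) -> np.ndarray:
        return self.encode(expr_panel, c=c).mu

    # -- persistence ---------------------------------------------------------

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters)}
        arrays["gene_meta"] = np.array(
            [self.g_st, self.g_sc, self.g_cov, int(self.trained)]
        )
        if self.sc_gene_names is not None:
            arrays["sc_gene_names"] = np.asarray(self.sc_gene_names, dtype="U64")
        if self.covet_gene_names is not None:
            arrays["covet_gene_names"] = np.asarray(self.covet_gene_names, dtype="U64")
        np.savez_compressed(out_dir / "weights.npz", **arrays)
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh)
        if self.loss_history:
            import csv

            with open(out_dir / "loss_log.csv", "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(self.loss_history[0]))
                writer.writeheader()
                writer.writerows(self.loss_history)

    @classmethod
    def load(cls, model_dir) -> "EnviModel":
        model_dir = Path(model_dir)
        with open(model_dir / "config.yaml") as fh:
            raw = yaml.safe_load(fh)
        raw["hidden_layers"] = tuple(raw["hidden_layers"])
        config = EnviConfig(**raw)
        data = np.load(model_dir / "weights.npz")
        g_st, g_sc, g_cov, trained = (int(v) for v in data["gene_meta"])
        model = cls(g_st, g_sc, g_cov, config)
        for i, p in enumerate(model.parameters):
            p.data = data[f"param_{i}"]
        model.trained = bool(trained)
        if "sc_gene_names" in data:
            model.sc_gene_names = data["sc_gene_names"].astype(object)
        if "covet_gene_names" in data:
            model.covet_gene_names = data["covet_gene_names"].astype(object)
        return model


def _fill_tril(tri: Tensor, g: int, tril_idx) -> Tensor:
    """Scatter (b, g(g+1)/2) free values into the lower triangle of (b, g, g)."""
    b = tri.shape[0]
    rows, cols = tril_idx
    data = np.zeros((b, g, g))
    data[:, rows, cols] = tri.data
    out = Tensor(data, parents=(tri,))

    def bwd(grad):
        tri._accumulate(grad[:, rows, cols])

    out._backward = bwd
    return out


def _batch_gramian(L: Tensor) -> Tensor:
    """L @ L^T per batch element for a (b, g, g) Tensor."""
    b, g, _ = L.shape
    # implemented with a single matmul on a block arrangement is not worth
    # the bookkeeping at g<=64; use the transpose trick via reshape instead
    Lt = _transpose_last2(L)
    return _bmm(L, Lt)


def _transpose_last2(t: Tensor) -> Tensor:
    out = Tensor(np.swapaxes(t.data, -1, -2), parents=(t,))

    def bwd(g):
        t._accumulate(np.swapaxes(g, -1, -2))

    out._backward = bwd
    return out


def _bmm(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            b._accumulate(np.swapaxes(a.data, -1, -2) @ g)

    out._backward = bwd
    return out


def select_hvg_union(
    sc: SingleCellDataset, panel_genes, n_top: int = 2048
) -> SingleCellDataset:
    """Subset the single-cell data to the union of its top HVGs and the panel.

    Dispersion-based ranking on log1p counts. Keeps panel genes regardless
    of rank; preserves the original gene order of the retained columns.
    """
    expr = np.log1p(sc.counts)
    mean = expr.mean(axis=0)
    var = expr.var(axis=0)
    disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    rank = np.argsort(-disp, kind="stable")[: min(n_top, sc.n_genes)]
    keep = np.zeros(sc.n_genes, dtype=bool)
    keep[rank] = True
    keep[sc.gene_indices(panel_genes)] = True
    idx = np.flatnonzero(keep)
    return SingleCellDataset(
        counts=sc.counts[:, idx],
        gene_names=sc.gene_names[idx],
        labels=sc.labels,
    )


def train(
    spatial: SpatialDataset,
    sc: SingleCellDataset,
    config: EnviConfig | None = None,
    log_every: int = 100,
) -> EnviModel:
    """Fit ENVI on a spatial / single-cell dataset pair.

    The single-cell genes are reordered so the spatial panel occupies the
    first ``g_st`` columns (the shared output units). COVET MSQR targets
    for every spatial cell are computed once before optimization. Training
    runs ``config.steps`` ADAM steps on batches of ``config.batch_size``
    cells, half sampled (with replacement) from each modality.
    Deterministic for a fixed seed in single-threaded execution.
    """
    if config is None:
        config = EnviConfig()
    panel_in_sc = match_panel(spatial, sc)  # raises if any panel gene missing
    # reorder: panel first (in panel order), then the remaining sc genes
    rest = np.setdiff1d(np.arange(sc.n_genes), panel_in_sc)
    order = np.concatenate([panel_in_sc, rest])
    sc_counts = sc.counts[:, order]
    sc_genes = sc.gene_names[order]

    g_st = spatial.n_genes
    g_sc = sc_counts.shape[1]

    covet_genes = highly_variable_panel_genes(spatial, config.covet_genes)
    covets = covet_from_dataset(
        spatial,
        k=config.covet_k,
        niche_genes=covet_genes,
        transform=config.covet_transform,
    )
    msqr_targets = covets.sqrt_matrices
    g_cov = msqr_targets.shape[1]

    model = EnviModel(g_st, g_sc, g_cov, config)
    model.sc_gene_names = sc_genes
    model.covet_gene_names = np.asarray(covet_genes, dtype=object)

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters, lr=config.learning_rate)
    half = config.batch_size // 2
    st_expr_all = spatial.counts
    sc_panel_all = sc_counts[:, :g_st]

    for step in range(config.steps):
        lr = config.learning_rate
        if (
            config.final_quarter_lr is not None
            and step >= config.steps * 3 // 4
        ):
            lr = config.final_quarter_lr
        ist = rng.integers(0, spatial.n_cells, size=half)
        isc = rng.integers(0, sc.n_cells, size=half)
        loss, comps = model.elbo_loss(
            st_expr_all[ist],
            msqr_targets[ist],
            sc_panel_all[isc],
            sc_counts[isc],
            rng,
        )
        opt.zero_grad()
        try:
            loss.backward()
        except FloatingPointError as err:  # pragma: no cover - defensive
            raise FloatingPointError(f"divergence at step {step}: {err}") from err
        opt.step(lr=lr)
        if step % log_every == 0 or step == config.steps - 1:
            model.loss_history.append({"step": step, **comps})

    model.trained = config.steps > 0
    return model
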