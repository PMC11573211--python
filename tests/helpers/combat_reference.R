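#!/usr/bin/env Rscript
# Independent ComBat oracle: reads a features x samples CSV and a batch
# label file, runs sva::ComBat (parametric priors, no covariates), writes
# the corrected matrix as CSV.  Usage:
#   Rscript combat_reference.R data.csv batch.txt out.csv
suppressMessages(library(sva))
args <- commandArgs(trailingOnly = TRUE)
dat <- as.matrix(read.csv(args[1], row.names = 1, check.names = FALSE))
batch <- scan(args[2], what = character(), quiet = TRUE)
out <- ComBat(dat = dat, batch = batch, mod = NULL, par.prior = TRUE, prior.plots = FALSE)
write.csv(out, args[3])
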