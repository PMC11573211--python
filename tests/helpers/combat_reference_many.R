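#!/usr/bin/env Rscript
# Batch ComBat oracle: reads a task list file where each line is
#   <data.csv>TAB<batch.txt>TAB<out.csv>
# and runs sva::ComBat (parametric, no covariates) for each task.
suppressMessages(library(sva))
tasks <- readLines(commandArgs(trailingOnly = TRUE)[1])
for (line in tasks) {
  f <- strsplit(line, "\t")[[1]]
  dat <- as.matrix(read.csv(f[1], row.names = 1, check.names = FALSE))
  batch <- scan(f[2], what = character(), quiet = TRUE)
  out <- ComBat(dat = dat, batch = batch, mod = NULL, par.prior = TRUE,
                prior.plots = FALSE)
  write.csv(out, f[3])
}
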