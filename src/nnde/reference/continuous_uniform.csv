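dv_type,iv_dist,sample_size,n_iv,shape,criterion_metric,criterion_threshold,de_proportion
continuous,uniform,50,3,"(2)",R2,0.1,0.0
continuous,uniform,50,3,"(7)",R2,0.1,0.0
continuous,uniform,50,3,"(30)",R2,0.1,0.001
continuous,uniform,50,3,"(10,10)",R2,0.1,0.004
continuous,uniform,50,3,"(50,50)",R2,0.1,0.022
continuous,uniform,50,5,"(2)",R2,0.1,0.007
continuous,uniform,50,5,"(7)",R2,0.1,0.004
continuous,uniform,50,5,"(30)",R2,0.1,0.01
continuous,uniform,50,5,"(10,10)",R2,0.1,0.007
continuous,uniform,50,5,"(50,50)",R2,0.1,0.023
continuous,uniform,50,10,"(2)",R2,0.1,0.008
continuous,uniform,50,10,"(7)",R2,0.1,0.013
continuous,uniform,50,10,"(30)",R2,0.1,0.016
continuous,uniform,50,10,"(10,10)",R2,0.1,0.015
continuous,uniform,50,10,"(50,50)",R2,0.1,0.03
continuous,uniform,100,3,"(2)",R2,0.1,0.0
continuous,uniform,100,3,"(7)",R2,0.1,0.0
continuous,uniform,100,3,"(30)",R2,0.1,0.0
continuous,uniform,100,3,"(10,10)",R2,0.1,0.0
continuous,uniform,100,3,"(50,50)",R2,0.1,0.004
continuous,uniform,100,5,"(2)",R2,0.1,0.0
continuous,uniform,100,5,"(7)",R2,0.1,0.0
continuous,uniform,100,5,"(30)",R2,0.1,0.0
continuous,uniform,100,5,"(10,10)",R2,0.1,0.0
continuous,uniform,100,5,"(50,50)",R2,0.1,0.004
continuous,uniform,100,10,"(2)",R2,0.1,0.0
continuous,uniform,100,10,"(7)",R2,0.1,0.0
continuous,uniform,100,10,"(30)",R2,0.1,0.0
continuous,uniform,100,10,"(10,10)",R2,0.1,0.0
continuous,uniform,100,10,"(50,50)",R2,0.1,0.012
continuous,uniform,200,3,"(2)",R2,0.1,0.0
continuous,uniform,200,3,"(7)",R2,0.1,0.0
continuous,uniform,200,3,"(30)",R2,0.1,0.0
continuous,uniform,200,3,"(10,10)",R2,0.1,0.0
continuous,uniform,200,3,"(50,50)",R2,0.1,0.001
continuous,uniform,200,5,"(2)",R2,0.1,0.0
continuous,uniform,200,5,"(7)",R2,0.1,0.0
continuous,uniform,200,5,"(30)",R2,0.1,0.0
continuous,uniform,200,5,"(10,10)",R2,0.1,0.0
continuous,uniform,200,5,"(50,50)",R2,0.1,0.0
continuous,uniform,200,10,"(2)",R2,0.1,0.0
continuous,uniform,200,10,"(7)",R2,0.1,0.0
continuous,uniform,200,10,"(30)",R2,0.1,0.0
continuous,uniform,200,10,"(10,10)",R2,0.1,0.0
continuous,uniform,200,10,"(50,50)",R2,0.1,0.0
continuous,uniform,500,3,"(2)",R2,0.1,0.0
continuous,uniform,500,3,"(7)",R2,0.1,0.0
continuous,uniform,500,3,"(30)",R2,0.1,0.0
continuous,uniform,500,3,"(10,10)",R2,0.1,0.0
continuous,uniform,500,3,"(50,50)",R2,0.1,0.0
continuous,uniform,500,5,"(2)",R2,0.1,0.0
continuous,uniform,500,5,"(7)",R2,0.1,0.0
continuous,uniform,500,5,"(30)",R2,0.1,0.0
continuous,uniform,500,5,"(10,10)",R2,0.1,0.0
continuous,uniform,500,5,"(50,50)",R2,0.1,0.0
continuous,uniform,500,10,"(2)",R2,0.1,0.0
continuous,uniform,500,10,"(7)",R2,0.1,0.0
continuous,uniform,500,10,"(30)",R2,0.1,0.0
continuous,uniform,500,10,"(10,10)",R2,0.1,0.0
continuous,uniform,500,10,"(50,50)",R2,0.1,0.0
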