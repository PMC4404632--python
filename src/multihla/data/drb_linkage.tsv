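dr_group	drb1_allele	paralog_allele	observed_count
DR52	DRB1*03:01:01	DRB3*02:02:01	1
DR52	DRB1*11:01:01	DRB3*02:02:01	3
DR52	DRB1*11:19:01	DRB3*02:02:01	1
DR52	DRB1*12:01:01/*12:10	DRB3*01:01:02	4
DR52	DRB1*12:01:01/*12:10	DRB3*01:12	1
DR52	DRB1*12:02:01	DRB3*03:01:03	3
DR52	DRB1*13:01:01	DRB3*01:01:02	1
DR52	DRB1*13:02:01	DRB3*03:01:01	2
DR52	DRB1*13:07:01	DRB3*02:02:01	1
DR52	DRB1*14:02:01	DRB3*02:02:01	1
DR52	DRB1*14:03:01	DRB3*01:01:02	2
DR52	DRB1*14:05:01	DRB3*02:02:01	1
DR52	DRB1*14:06:01	DRB3*02:02:01	1
DR52	DRB1*14:07:01	DRB3*02:02:01	1
DR52	DRB1*14:54:01	DRB3*02:02:01	1
DR53	DRB1*04:01:01	DRB4*01:02	1
DR53	DRB1*04:03:01	DRB4*01:03:01	1
DR53	DRB1*04:04:01	DRB4*01:03:01	1
DR53	DRB1*04:05:01	DRB4*01:03:01	8
DR53	DRB1*04:05:01	DRB4*01:03:02	2
DR53	DRB1*04:06:01	DRB4*01:03:01	6
DR53	DRB1*04:06:01	DRB4*01:03:02	1
DR53	DRB1*04:07:01/*04:92	DRB4*01:03:02	1
DR53	DRB1*04:10:01/*04:10:03	DRB4*01:03:01	1
DR53	DRB1*07:01:01	DRB4*01:03:01	2
DR53	DRB1*09:01:02/*09:21	DRB4*01:03:02	10
DR53	DRB1*09:01:02/*09:21	DRB4*01:03:01	2
DR51	DRB1*15:01:01	DRB5*01:01:01	4
DR51	DRB1*15:02:01	DRB5*01:02	5
DR51	DRB1*16:02:01	DRB5*02:02	1
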