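speed_m_s,entity,fx_n_per_kg,fy_n_per_kg,fz_n_per_kg
3,ankle_jcf,6.3971,-9.5957,79.1644
3,semimembranosus,-2.0051,-3.0077,9.3238
3,semitendinosus,-0.9975,-0.7980,3.7905
3,biceps_femoris_long_head,1.8010,-1.5008,5.5230
3,biceps_femoris_short_head,0.6015,-0.4010,1.8648
3,sartorius,-0.4512,0.3008,1.3986
3,tensor_fasciae_latae,0.4984,0.2990,1.9137
3,gracilis,-0.4494,0.1498,1.4232
3,soleus,2.2556,-13.5339,-42.8573
3,tibialis_posterior,1.2036,-3.0089,-11.5541
3,tibialis_anterior,0.3995,1.1985,-3.7953
3,flexor_digitorum,0.1498,-0.5991,-2.9357
3,flexor_hallucis,0.6018,-1.5044,-5.7771
3,peroneus_brevis,1.0046,-0.5023,-4.8722
3,peroneus_longus,1.1980,-1.5973,-7.7468
3,peroneus_tertius,0.1998,0.1998,-0.9592
3,extensor_digitorum,0.1998,0.5993,-1.8976
4,ankle_jcf,8.3163,-12.4744,102.9137
4,semimembranosus,-2.2056,-3.3084,10.2562
4,semitendinosus,-1.2469,-0.9975,4.7382
4,biceps_femoris_long_head,2.1012,-1.7510,6.4435
4,biceps_femoris_short_head,0.7519,-0.5013,2.3310
4,sartorius,-0.6015,0.4010,1.8648
4,tensor_fasciae_latae,0.4984,0.2990,1.9137
4,gracilis,-0.5993,0.1998,1.8976
4,soleus,2.7569,-16.5414,-52.3811
4,tibialis_posterior,1.4041,-3.5104,-13.4798
4,tibialis_anterior,0.3496,1.0487,-3.3209
4,flexor_digitorum,0.1997,-0.7988,-3.9143
4,flexor_hallucis,0.7522,-1.8806,-7.2213
4,peroneus_brevis,1.2055,-0.6027,-5.8467
4,peroneus_longus,1.3477,-1.7969,-8.7152
4,peroneus_tertius,0.2398,0.2398,-1.1511
4,extensor_digitorum,0.1998,0.5993,-1.8976
5,ankle_jcf,10.2354,-15.3531,126.6630
5,semimembranosus,-2.4061,-3.6092,11.1886
5,semitendinosus,-1.3716,-1.0973,5.2120
5,biceps_femoris_long_head,2.4013,-2.0011,7.3641
5,biceps_femoris_short_head,0.9023,-0.6015,2.7971
5,sartorius,-0.6617,0.4411,2.0512
5,tensor_fasciae_latae,0.6229,0.3738,2.3921
5,gracilis,-0.6592,0.2197,2.0874
5,soleus,3.2582,-19.5489,-61.9050
5,tibialis_posterior,1.6047,-4.0119,-15.4055
5,tibialis_anterior,0.2996,0.8989,-2.8464
5,flexor_digitorum,0.2496,-0.9986,-4.8929
5,flexor_hallucis,0.9027,-2.2567,-8.6656
5,peroneus_brevis,1.4064,-0.7032,-6.8211
5,peroneus_longus,1.4975,-1.9966,-9.6836
5,peroneus_tertius,0.2998,0.2998,-1.4388
5,extensor_digitorum,0.2197,0.6592,-2.0874
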