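row_id,kind,statistic,df1,df2,n,printed,cmp,derivable,label
c1_anova_condition_p,f_p,11.14,1,35,,0.002,eq,1,cohort1 ANOVA main effect of condition (social > nonsocial)
c1_anova_region_p,f_p,7.05,1,35,,0.012,eq,1,cohort1 ANOVA main effect of region (left > right)
c1_anova_half_p,f_p,7.02,1,35,,0.012,eq,1,cohort1 ANOVA main effect of half (second > first)
c1_anova_condition_eta,eta_f,11.14,1,35,,0.24,eq,1,cohort1 partial eta squared for condition
c1_anova_region_eta,eta_f,7.05,1,35,,0.17,eq,1,cohort1 partial eta squared for region
c1_anova_half_eta,eta_f,7.02,1,35,,0.17,eq,1,cohort1 partial eta squared for half
c1_subsample_half_p,f_p,10.87,1,33,,0.002,eq,1,cohort1 Mullen subsample half effect
c1_theta_nonverbal_p,pearson_p,0.39,,,34,0.022,eq,1,cohort1 frontal theta change vs nonverbal t
c1_theta_verbal_p,pearson_p,0.27,,,34,0.12,eq,1,cohort1 frontal theta change vs verbal t
c1_attended_t_p,t_p,0.93,33,,,0.36,eq,1,cohort1 one-sample t on attended-proportion change
c1_attended_nonverbal_p,pearson_p,-0.06,,,34,0.63,eq,0,cohort1 attended change vs nonverbal t (printed p inconsistent with printed r and n)
c1_attended_theta_p,pearson_p,0.089,,,34,0.62,eq,1,cohort1 attended change vs frontal theta change
c1_alpha_nonverbal_p,pearson_p,-0.22,,,34,0.22,eq,1,cohort1 alpha change vs nonverbal t
c1_alpha_verbal_p,pearson_p,-0.21,,,34,0.23,eq,1,cohort1 alpha change vs verbal t
c1_steiger_verbal_p,z_p,2.35,,,,0.009,eq,1,cohort1 Steiger theta-vs-alpha comparison (verbal)
c1_steiger_nonverbal_p,z_p,1.83,,,,0.033,eq,1,cohort1 Steiger theta-vs-alpha comparison (nonverbal)
c1_posterior_nonverbal_p,pearson_p,0.16,,,34,0.38,eq,1,cohort1 posterior theta change vs nonverbal t
c1_posterior_verbal_p,pearson_p,0.20,,,34,0.27,eq,1,cohort1 posterior theta change vs verbal t
c1_rep_social_social_p,pearson_p,0.40,,,43,0.007,eq,1,cohort1 within-social vs social repetition change
c1_rep_social_nonsocial_p,pearson_p,-0.08,,,32,0.65,eq,1,cohort1 within-social vs nonsocial repetition change
c1_rep_nonsocial_nonsocial_p,pearson_p,0.56,,,38,0.001,le,1,cohort1 within-nonsocial vs nonsocial repetition change (p < .001)
c1_rep_nonsocial_social_p,pearson_p,0.12,,,30,0.52,eq,1,cohort1 within-nonsocial vs social repetition change
c2_theta_nonverbal_p,pearson_p,0.55,,,14,0.043,eq,1,cohort2 frontal theta change vs 24m nonverbal t
c2_theta_verbal_p,pearson_p,0.58,,,14,0.029,eq,1,cohort2 frontal theta change vs 24m verbal t
c2_theta_nonverbal_cov_p,pearson_p,0.51,,,11,0.08,eq,0,cohort2 covaried correlation (df convention for the partial not stated)
c2_theta_verbal_cov_p,pearson_p,0.69,,,11,0.009,eq,0,cohort2 covaried correlation (df convention for the partial not stated)
c2_posterior_nonverbal_p,pearson_p,0.57,,,14,0.034,eq,1,cohort2 posterior theta change vs nonverbal t
c2_posterior_verbal_p,pearson_p,0.70,,,14,0.006,eq,1,cohort2 posterior theta change vs verbal t
c2_alpha_nonverbal_p,pearson_p,0.28,,,14,0.33,eq,1,cohort2 alpha change vs nonverbal t
c2_alpha_verbal_p,pearson_p,0.31,,,14,0.28,eq,1,cohort2 alpha change vs verbal t
c2_attended_nonverbal_p,pearson_p,-0.21,,,14,0.48,eq,1,cohort2 attended change vs nonverbal t
c2_attended_verbal_p,pearson_p,-0.18,,,14,0.55,eq,1,cohort2 attended change vs verbal t
c3_nonverbal_theta_p,f_p,14.18,1,34,,0.001,eq,1,cohort3 ANCOVA theta predictor on 36m nonverbal
c3_nonverbal_theta_cov_p,f_p,13.02,1,33,,0.001,eq,1,cohort3 ANCOVA theta predictor with 12m covariate
c3_nonverbal_interaction_p,f_p,5.46,2,34,,0.01,eq,1,cohort3 ANCOVA theta-by-group interaction
c3_nonverbal_interaction_cov_p,f_p,4.97,1,33,,0.015,eq,0,cohort3 covaried interaction (printed p inconsistent with printed F and df)
c3_asd_nonverbal_p,pearson_p,0.91,,,7,0.005,eq,1,cohort3 ASD subgroup theta vs 36m nonverbal
c3_asd_nonverbal_var,var_from_r,0.91,,,7,82,eq,1,cohort3 ASD subgroup variance explained (percent)
c3_asd_verbal_p,pearson_p,0.81,,,7,0.029,eq,1,cohort3 ASD subgroup theta vs 36m verbal
c3_verbal_theta_p,f_p,2.84,1,34,,0.1,eq,1,cohort3 ANCOVA theta predictor on 36m verbal
c3_verbal_theta_cov_p,f_p,2.32,1,33,,0.14,eq,1,cohort3 covaried verbal predictor
c3_verbal_interaction_p,f_p,3.77,1,34,,0.036,eq,0,cohort3 verbal interaction (printed p inconsistent with printed F and df)
c3_verbal_interaction_cov_p,f_p,3.95,1,33,,0.032,eq,0,cohort3 covaried verbal interaction (printed p inconsistent with printed F and df)
c3_posterior_nonverbal_p,f_p,0.47,1,34,,0.50,eq,1,cohort3 posterior theta on 36m nonverbal
c3_alpha_nonverbal_p,f_p,3.57,1,34,,0.069,eq,0,cohort3 alpha on 36m nonverbal (recomputed 0.067 outside printed rounding)
c3_attended_nonverbal_p,f_p,1.25,1,34,,0.27,eq,1,cohort3 attended change on 36m nonverbal
c3_posterior_verbal_p,f_p,1.32,1,34,,0.26,eq,1,cohort3 posterior theta on 36m verbal
c3_alpha_verbal_p,f_p,3.64,1,34,,0.067,eq,0,cohort3 alpha on 36m verbal (recomputed 0.065 outside printed rounding)
c3_attended_verbal_p,f_p,0.38,1,34,,0.54,eq,1,cohort3 attended change on 36m verbal
c3_iq7_theta_p,f_p,5.27,1,25,,0.03,eq,1,cohort3 ANCOVA theta on 7y IQ
c3_iq7_interaction_p,f_p,0.34,1,25,,0.57,eq,1,cohort3 theta-by-risk interaction on 7y IQ
c3_iq7_posterior_p,f_p,0.43,1,25,,0.52,eq,1,cohort3 posterior theta on 7y IQ
c3_iq7_alpha_p,f_p,0.65,1,25,,0.43,eq,1,cohort3 alpha on 7y IQ
c3_iq7_attended_p,f_p,1.16,1,25,,0.29,eq,1,cohort3 attended change on 7y IQ
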